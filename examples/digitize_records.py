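"""Digitize text-valued EMR descriptors to numeric features.

A degree-graded symptom with a severity levels maps to 0 when absent and to
0.5 + x/(2a) at level x, so presence contributes a base 0.5 and severity the
rest; present/absent descriptors map to 1/0; a blank field stays missing
(NaN) because no information is not the same as no symptom.
"""

from emrcost import digitize_degree, digitize_table
from emrcost.records import ColumnSpec, RawRecord, Schema

print("degree conversion, a=3 levels (mild/moderate/severe):")
for x, term in enumerate(["absent", "mild", "moderate", "severe"]):
    y = digitize_degree(3, b=0 if x == 0 else 1, x=x)
    print(f"  {term:9s} -> {y:.4f}")

schema = Schema(columns=(
    ColumnSpec("age", "numeric"),
    ColumnSpec("smoking", "binary"),
    ColumnSpec("distension", "degree", levels=("mild", "moderate", "severe")),
))
records = [
    RawRecord({"age": 61.0, "smoking": "yes", "distension": "moderate"}),
    RawRecord({"age": 47.0, "smoking": "no", "distension": "none"}),
    RawRecord({"age": 70.0, "smoking": None, "distension": "severe"}),
]
fm = digitize_table(records, schema)
print("\ndigitized table (NaN = field missing in the record):")
print(fm.X.to_string())
print("\nnote row 2: a missing smoking field is NaN, not 0 —")
print("it is handed to the imputer instead of being read as 'non-smoker'.")
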