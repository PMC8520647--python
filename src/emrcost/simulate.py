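"""Synthetic EMR cohort generator.

Emulates a small oncology cohort with the 16-variable record layout the
package's pipeline expects: demographics (gender, age, months since bowel
surgery), current-illness descriptors with ordinal severities (urinary and
defecation symptoms, pathology grade, fever, medication intensity), binary
treatment and history flags (metastasis, radiotherapy, chemotherapy,
diabetes, hypertension, other surgery, smoking, drinking), a four-class
treatment-scheme label, and a continuous treatment cost.

The generative model is, per patient:

1. draw the treatment scheme from ``scheme_priors``;
2. draw each feature from its baseline distribution shifted by that scheme's
   entry in ``scheme_feature_effects`` (numeric features: additive mean
   shift; binary and degree features: additive shift on the presence logit,
   and for degree features also an exponential tilt of the severity-level
   distribution toward higher grades), plus fixed within-record couplings
   (comorbidity prevalence rises with age; smoking and drinking are more
   common in men);
3. set cost = scheme intercept + beta_scheme . z + Gaussian noise, where z is
   the *digitized* feature vector (so the regression stage's estimand is the
   exact coefficient vector used here);
4. blank each feature cell independently with probability ``missing_rate``
   (missing completely at random); scheme and cost are never blanked.

Costs are in thousands of currency units.  Everything is reproducible from
``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .records import ColumnSpec, RawRecord, Schema, read_records, write_records

__all__ = [
    "SimConfig",
    "default_schema",
    "default_config",
    "generate_records",
    "write_records",
    "read_records",
]

SCHEME_LABELS = ("systematic", "primary_chemo", "secondary_chemo", "targeted")

SEVERITY = ("mild", "moderate", "severe")


def default_schema() -> Schema:
    """The 16-variable record layout used throughout the package."""
    cols = (
        ColumnSpec("gender", "binary", tokens=("female", "male")),
        ColumnSpec("age", "numeric"),
        ColumnSpec("postop_months", "numeric"),
        ColumnSpec("urethral_symptoms", "degree", levels=SEVERITY),
        ColumnSpec("defecation_symptoms", "degree", levels=SEVERITY),
        ColumnSpec("pathology", "degree",
                   levels=("well_diff", "moderately_diff", "poorly_diff")),
        ColumnSpec("metastasis", "binary"),
        ColumnSpec("radiotherapy", "binary"),
        ColumnSpec("chemotherapy", "binary"),
        ColumnSpec("fever", "degree", levels=SEVERITY),
        ColumnSpec("medication", "degree", levels=("low", "medium", "high")),
        ColumnSpec("diabetes", "binary"),
        ColumnSpec("hypertension", "binary"),
        ColumnSpec("other_surgery", "binary"),
        ColumnSpec("smoking", "binary"),
        ColumnSpec("drinking", "binary"),
    )
    return Schema(columns=cols, scheme_labels=SCHEME_LABELS)


# Baseline feature distributions.  Numeric: (mean, sd, low clip, high clip).
# Binary: presence probability.  Degree: presence probability (severity levels
# start from a mildly decreasing base distribution and are tilted per scheme).
_NUMERIC_BASE = {
    "age": (62.0, 10.0, 20.0, 95.0),
    "postop_months": (18.0, 12.0, 0.0, 120.0),
}
_PRESENCE_BASE = {
    "gender": 0.55,
    "urethral_symptoms": 0.30,
    "defecation_symptoms": 0.50,
    "pathology": 0.90,
    "metastasis": 0.20,
    "radiotherapy": 0.30,
    "chemotherapy": 0.50,
    "fever": 0.25,
    "medication": 0.95,
    "diabetes": 0.20,
    "hypertension": 0.35,
    "other_surgery": 0.25,
    "smoking": 0.40,
    "drinking": 0.35,
}
_LEVEL_BASE = (0.5, 0.3, 0.2)  # P(level | present) before the scheme tilt

# Per-scheme distribution shifts: numeric features get an additive mean
# shift, binary/degree features a presence-logit shift (which for degree
# features also tilts the severity distribution).  Chosen so the four schemes
# are clinically plausible and separable but overlapping.
DEFAULT_SCHEME_EFFECTS: Dict[str, Dict[str, float]] = {
    # The chemo/radiotherapy flags record what the scheme prescribed, so they
    # are near-deterministic given the scheme (up to ~1% recording error);
    # disease-state variables (metastasis, pathology, symptoms) shift
    # probabilistically.
    # surgery-only systemic care: typically older patients judged unfit for
    # aggressive therapy; no chemo/radio, disease not metastatic
    "systematic": {
        "chemotherapy": -6.0, "radiotherapy": -5.0, "metastasis": -3.5,
        "age": 6.0,
    },
    # first-line chemotherapy: chemo certain, no radiotherapy
    "primary_chemo": {
        "chemotherapy": 6.0, "radiotherapy": -5.0, "metastasis": -3.0,
        "medication": 1.0, "defecation_symptoms": 0.8, "age": -2.0,
    },
    # second-line chemo after relapse: chemo + radiotherapy, metastatic,
    # longer postoperative history, more systemic symptoms
    "secondary_chemo": {
        "chemotherapy": 6.0, "radiotherapy": 6.0, "metastasis": 3.0,
        "fever": 1.0, "medication": 1.5, "postop_months": 15.0, "age": -2.0,
    },
    # targeted therapy: metastatic, poorly differentiated disease,
    # mostly without concurrent chemo/radiotherapy
    "targeted": {
        "metastasis": 5.0, "pathology": 2.0, "medication": 2.5,
        "chemotherapy": -3.0, "radiotherapy": -1.0,
        "urethral_symptoms": 1.0, "age": -6.0,
    },
}

# Per-scheme cost model on the digitized features: (intercept, sparse
# coefficient dict).  Thousands of currency units.  The cost drivers are the
# treatment variables (chemo, radio, medication), disease extent (metastasis,
# pathology) and demographics; six of the sixteen variables (gender, diabetes,
# hypertension, other surgery, smoking, drinking) carry no cost signal in any
# scheme and are independent of the scheme as well.
DEFAULT_COST_MODEL: Dict[str, Tuple[float, Dict[str, float]]] = {
    # base costs overlap (the pooled cost distribution is a single blob, not
    # four separated modes); what differs strongly between schemes is WHICH
    # features drive the cost and in which direction
    "systematic": (38.0, {
        "age": 0.30, "metastasis": 6.0, "medication": 8.0,
        "defecation_symptoms": 5.0, "pathology": 3.0,
        "postop_months": -0.05,
    }),
    "primary_chemo": (46.0, {
        "chemotherapy": 12.0, "medication": 2.0, "fever": 6.0,
        "postop_months": 0.15, "age": -0.25,
    }),
    "secondary_chemo": (50.0, {
        "radiotherapy": 10.0, "metastasis": 12.0, "medication": 10.0,
        "postop_months": -0.20, "chemotherapy": 6.0, "age": 0.10,
    }),
    "targeted": (58.0, {
        "metastasis": 18.0, "pathology": 12.0, "medication": 15.0,
        "age": -0.25, "urethral_symptoms": 5.0, "postop_months": 0.05,
    }),
}

# Within-record couplings (independent of scheme): comorbidity prevalence
# rises with age, and smoking/drinking are more common in men.  Expressed as
# additive logit terms evaluated on already-drawn fields.
_AGE_REF = 62.0
_COUPLINGS = {
    "diabetes": lambda drawn: 0.06 * (drawn["age"] - _AGE_REF),
    "hypertension": lambda drawn: 0.08 * (drawn["age"] - _AGE_REF),
    "smoking": lambda drawn: 1.2 * drawn["gender"] - 0.6,
    "drinking": lambda drawn: 1.0 * drawn["gender"] - 0.5,
}

DEFAULT_SCHEME_PRIORS = (0.35, 0.30, 0.20, 0.15)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic cohort.

    ``cost_coefficients`` maps scheme label -> (intercept, {feature: beta})
    on the digitized feature scale; ``scheme_feature_effects`` maps scheme
    label -> {feature: shift}.  ``noise_sd`` is the cost-noise standard
    deviation in the same (thousand-unit) currency scale; ``missing_rate``
    is the independent per-cell blanking probability.
    """

    n_records: int
    schema: Schema
    scheme_priors: Tuple[float, ...] = DEFAULT_SCHEME_PRIORS
    scheme_feature_effects: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: DEFAULT_SCHEME_EFFECTS)
    cost_coefficients: Dict[str, Tuple[float, Dict[str, float]]] = field(
        default_factory=lambda: DEFAULT_COST_MODEL)
    noise_sd: float = 6.0
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 1:
            raise ConfigError(f"n_records: must be >= 1, got {self.n_records}")
        labels = self.schema.scheme_labels
        if labels is None:
            raise ConfigError("schema: scheme_labels must be declared")
        if len(self.scheme_priors) != len(labels):
            raise ConfigError(
                f"scheme_priors: expected {len(labels)} entries, "
                f"got {len(self.scheme_priors)}")
        if any(p < 0 for p in self.scheme_priors):
            raise ConfigError("scheme_priors: negative probability")
        if abs(sum(self.scheme_priors) - 1.0) > 1e-12:
            raise ConfigError(
                f"scheme_priors: sum {sum(self.scheme_priors)!r} != 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(
                f"missing_rate: must be in [0, 1), got {self.missing_rate}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd: must be > 0, got {self.noise_sd}")
        for label in labels:
            if label not in self.cost_coefficients:
                raise ConfigError(f"cost_coefficients: no entry for {label!r}")
        for mapping_name in ("scheme_feature_effects", "cost_coefficients"):
            mapping = getattr(self, mapping_name)
            for label, entry in mapping.items():
                if label not in labels:
                    raise ConfigError(
                        f"{mapping_name}: unknown scheme {label!r}")
                feats = entry[1] if mapping_name == "cost_coefficients" else entry
                for name in feats:
                    if name not in self.schema:
                        raise ConfigError(
                            f"{mapping_name}[{label!r}]: unknown feature {name!r}")


def default_config(n_records: int = 240, seed: int = 0, **overrides) -> SimConfig:
    """A :class:`SimConfig` with the package's standard cohort settings."""
    cfg = SimConfig(n_records=n_records, schema=default_schema(), seed=seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p: float) -> float:
    return np.log(p / (1.0 - p))


def _draw_feature(rng: np.random.Generator, spec: ColumnSpec, effect: float):
    """One raw feature value under a scheme shift. Returns (raw, digitized)."""
    if spec.kind == "numeric":
        mean, sd, lo, hi = _NUMERIC_BASE[spec.name]
        value = float(np.clip(rng.normal(mean + effect, sd), lo, hi))
        value = round(value, 1)
        return value, value
    p = _sigmoid(_logit(_PRESENCE_BASE[spec.name]) + effect)
    present = rng.random() < p
    if spec.kind == "binary":
        return spec.tokens[int(present)], float(present)
    if not present:
        return spec.absent, 0.0
    base = np.asarray(_LEVEL_BASE[: spec.a], dtype=float)
    base = base / base.sum()
    tilt = base * np.exp(effect * np.arange(1, spec.a + 1) / spec.a)
    tilt = tilt / tilt.sum()
    x = int(rng.choice(spec.a, p=tilt)) + 1
    return spec.levels[x - 1], 0.5 + x / (2 * spec.a)


def generate_records(config: SimConfig):
    """Generate ``config.n_records`` synthetic patient records.

    Returns a list of :class:`RawRecord`.  Cost is computed from the
    digitized (not raw-text) feature values before any blanking, so complete
    knowledge of the features recovers the configured coefficients exactly up
    to noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = config.schema.scheme_labels
    records = []
    for _ in range(config.n_records):
        scheme = labels[rng.choice(len(labels), p=np.asarray(config.scheme_priors))]
        effects = config.scheme_feature_effects.get(scheme, {})
        raw = {}
        digitized = {}
        for spec in config.schema.columns:
            effect = effects.get(spec.name, 0.0)
            coupling = _COUPLINGS.get(spec.name)
            if coupling is not None:
                effect += coupling(digitized)
            raw[spec.name], digitized[spec.name] = _draw_feature(
                rng, spec, effect)
        intercept, betas = config.cost_coefficients[scheme]
        cost = intercept + sum(b * digitized[n] for n, b in betas.items())
        cost += rng.normal(0.0, config.noise_sd)
        if config.missing_rate > 0:
            for spec in config.schema.columns:
                if rng.random() < config.missing_rate:
                    raw[spec.name] = None
        records.append(RawRecord(fields=raw, scheme=scheme, cost=float(cost)))
    return records
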