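"""Logistic-regression scoring models for candidate variants.

Two fixed-form logistic models — one for SNVs, one for indels — map a
candidate's feature vector to the probability that it is a real variant:

    p = 1 / (1 + exp(-(intercept + sum_i coef_i * x_i)))

Default intercepts and coefficients are the caller's published values and
may be overridden, per parameter, through a flat key/value config file
(``snv.ratio_score = 11.0``). The same dialect is written by the retrain
module, closing the retrain -> call loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

SNV_FEATURES = ("ratio_score", "base_qual", "mean_avnqs", "rel_pos", "titv")
INDEL_FEATURES = ("ratio_score", "strand_dir", "mean_avnqs", "seq_entropy", "mean_var_rate")

DEFAULT_SNV_INTERCEPT = -6.6404
DEFAULT_SNV_COEFFICIENTS = {
    "ratio_score": 11.1192,
    "base_qual": 0.25579,
    "mean_avnqs": 0.12896,
    "rel_pos": 0.69106,
    "titv": 0.48511,
}

DEFAULT_INDEL_INTERCEPT = -7.1085
DEFAULT_INDEL_COEFFICIENTS = {
    "ratio_score": 6.22804,
    "strand_dir": 2.21407,
    "mean_avnqs": 0.07777,
    "seq_entropy": 0.1479,
    "mean_var_rate": -2.13305,
}


@dataclass
class LogisticModel:
    """Intercept plus named coefficients for one variant class."""

    model_kind: str  # "SNV" or "INDEL"
    intercept: float
    coefficients: Dict[str, float]

    def __post_init__(self) -> None:
        expected = SNV_FEATURES if self.model_kind == "SNV" else INDEL_FEATURES
        if tuple(self.coefficients) != expected:
            got = tuple(self.coefficients)
            raise ValueError(
                f"{self.model_kind} model requires features {expected}, got {got}"
            )

    @classmethod
    def snv_default(cls) -> "LogisticModel":
        return cls("SNV", DEFAULT_SNV_INTERCEPT, dict(DEFAULT_SNV_COEFFICIENTS))

    @classmethod
    def indel_default(cls) -> "LogisticModel":
        return cls("INDEL", DEFAULT_INDEL_INTERCEPT, dict(DEFAULT_INDEL_COEFFICIENTS))


def logistic_score(m: LogisticModel, features: Mapping[str, float]) -> float:
    """Probability in (0, 1) that the candidate is a real variant."""
    z = m.intercept
    for name, coef in m.coefficients.items():
        if name not in features:
            raise KeyError(f"feature {name!r} missing from input to {m.model_kind} model")
        z += coef * features[name]
    # numerically safe sigmoid
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def _parse_config_lines(text: str) -> Dict[Tuple[str, str], float]:
    entries: Dict[Tuple[str, str], float] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'model.param = value'")
        key, val = (part.strip() for part in line.split("=", 1))
        if "." not in key:
            raise ValueError(f"config line {lineno}: key must be 'model.param', got {key!r}")
        model, param = key.split(".", 1)
        model = model.lower()
        if model not in ("snv", "indel"):
            raise ValueError(f"config line {lineno}: unknown model {model!r} (snv or indel)")
        valid = ("intercept",) + (SNV_FEATURES if model == "snv" else INDEL_FEATURES)
        if param not in valid:
            raise ValueError(
                f"config line {lineno}: unknown parameter {param!r} for {model} model; "
                f"valid names: {', '.join(valid)}"
            )
        entries[(model, param)] = float(val)
    return entries


def load_model_config(path: Optional[str] = None) -> Tuple[LogisticModel, LogisticModel]:
    """Return (snv_model, indel_model): defaults, with per-parameter overrides.

    An absent path yields the default models. A present file overrides only
    the parameters it names; unknown names are a fatal error listing the
    valid ones.
    """
    snv = LogisticModel.snv_default()
    indel = LogisticModel.indel_default()
    if path is None:
        return snv, indel
    with open(path) as fh:
        entries = _parse_config_lines(fh.read())
    for (model, param), value in entries.items():
        target = snv if model == "snv" else indel
        if param == "intercept":
            target.intercept = value
        else:
            target.coefficients[param] = value
    return snv, indel


def save_model_config(path: str, snv: LogisticModel, indel: LogisticModel) -> None:
    """Write both models in the flat config dialect (full-precision repr)."""
    lines = []
    for prefix, m in (("snv", snv), ("indel", indel)):
        lines.append(f"{prefix}.intercept = {m.intercept!r}")
        for name, coef in m.coefficients.items():
            lines.append(f"{prefix}.{name} = {coef!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
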