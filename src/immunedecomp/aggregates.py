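"""Aggregate infiltration indices (TIS, IIS, APM) and log-ratio scores.

The T-cell infiltration score (TIS) is the mean of the row-standardized
ssGSEA scores of nine T-cell subsets; the overall immune infiltration score
(IIS) extends that mean over the innate and adaptive compartments (the
gamma-delta and follicular-helper T-cell signatures are excluded from both
because several of their genes are expressed in healthy brain tissue).  The
APM activity of a sample is simply the ssGSEA score of the seven-gene
antigen-presenting-machinery signature, passed through unchanged.

Because ssGSEA scores behave like log-scale abundances, the difference of
two scores is interpreted as the log of a cell-count ratio; `log_ratio`
implements that with the CD8+T/Treg and Th17/Th2 presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AggregateDefinition",
    "TIS_CONSTITUENTS",
    "IIS_CONSTITUENTS",
    "AGGREGATE_EXCLUSIONS",
    "tis_definition",
    "iis_definition",
    "standardize",
    "aggregate",
    "compute_aggregates",
    "log_ratio",
    "LOG_RATIO_PRESETS",
    "median_split",
    "load_definitions",
]

#: The nine T-cell subset signatures entering TIS.
TIS_CONSTITUENTS = (
    "CD8 T cells",
    "T helper cells",
    "T cells",
    "T central memory",
    "T effector memory",
    "Th1 cells",
    "Th2 cells",
    "Th17 cells",
    "Treg",
)

#: Innate/adaptive signatures that, together with the TIS subsets, form IIS.
IIS_CONSTITUENTS = TIS_CONSTITUENTS + (
    "Macrophages",
    "DC",
    "aDC",
    "iDC",
    "pDC",
    "B cells",
    "Cytotoxic cells",
    "Eosinophils",
    "Mast cells",
    "Neutrophils",
    "NK cells",
    "NK CD56bright cells",
    "NK CD56dim cells",
)

#: Signatures deliberately excluded from both aggregates.
AGGREGATE_EXCLUSIONS = ("T gamma delta", "T follicular helper")


@dataclass(frozen=True)
class AggregateDefinition:
    """A named mean (or sum) over standardized signature rows."""

    name: str
    constituents: tuple[str, ...]
    exclusions: tuple[str, ...] = ()
    reduction: str = "mean"

    def __post_init__(self) -> None:
        if not self.constituents:
            raise ValueError(f"aggregate {self.name!r} has no constituents")
        object.__setattr__(self, "constituents", tuple(self.constituents))
        object.__setattr__(self, "exclusions", tuple(self.exclusions))
        if set(self.constituents) & set(self.exclusions):
            raise ValueError(
                f"aggregate {self.name!r}: constituents overlap exclusions"
            )
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


def tis_definition(reduction: str = "mean") -> AggregateDefinition:
    return AggregateDefinition(
        "TIS", TIS_CONSTITUENTS, AGGREGATE_EXCLUSIONS, reduction
    )


def iis_definition(reduction: str = "mean") -> AggregateDefinition:
    return AggregateDefinition(
        "IIS", IIS_CONSTITUENTS, AGGREGATE_EXCLUSIONS, reduction
    )


def standardize(scores: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores: each signature row gets mean 0, sd 1 across samples.

    Uses the sample standard deviation (n-1 denominator).  A zero-variance
    row is an error because its z-scores are undefined.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardize")
    sd = scores.std(axis=1, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance signature row(s): {dead}")
    return scores.sub(scores.mean(axis=1), axis=0).div(sd, axis=0)


def aggregate(z: pd.DataFrame, definition: AggregateDefinition) -> pd.Series:
    """Per-sample reduction over the definition's constituent rows of ``z``."""
    missing = [c for c in definition.constituents if c not in z.index]
    if missing:
        raise ValueError(
            f"aggregate {definition.name!r}: missing constituent row(s) {missing}"
        )
    block = z.loc[list(definition.constituents)]
    values = block.sum(axis=0) if definition.reduction == "sum" else block.mean(axis=0)
    values.name = definition.name
    return values


def compute_aggregates(
    scores: pd.DataFrame,
    definitions: list[AggregateDefinition] | None = None,
    apm_scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Standardize a score matrix and evaluate TIS/IIS (plus optional APM row).

    ``apm_scores`` — the raw ssGSEA scores of the APM signature — are
    appended unchanged, since APM is not a standardized composite.
    """
    definitions = definitions or [tis_definition(), iis_definition()]
    z = standardize(scores)
    rows = [aggregate(z, d) for d in definitions]
    if apm_scores is not None:
        apm_scores = apm_scores.rename("APM")
        rows.append(apm_scores)
    return pd.DataFrame(rows)


#: Shipped numerator/denominator pairs for `log_ratio`.
LOG_RATIO_PRESETS = {
    "CD8_T_to_Treg": ("CD8 T cells", "Treg"),
    "Th17_to_Th2": ("Th17 cells", "Th2 cells"),
}


def log_ratio(scores: pd.DataFrame, numerator: str, denominator: str) -> pd.Series:
    """score(numerator) - score(denominator), read as log(count_a / count_b)."""
    for name in (numerator, denominator):
        if name not in scores.index:
            raise KeyError(f"unknown signature name {name!r}")
    out = scores.loc[numerator] - scores.loc[denominator]
    out.name = f"log({numerator}/{denominator})"
    return out


def median_split(values: pd.Series) -> pd.Series:
    """'low' for values <= median, 'high' above; group sizes differ by <= 1
    when values are distinct."""
    med = float(np.median(values.to_numpy()))
    return pd.Series(
        np.where(values.to_numpy() <= med, "low", "high"),
        index=values.index,
        name=f"{values.name}_median_split",
    )


def load_definitions(path: str | Path) -> list[AggregateDefinition]:
    """Read aggregate definitions from a YAML/JSON config.

    Expected layout: a list of mappings with keys ``name``, ``constituents``
    and optional ``exclusions`` / ``reduction``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError("aggregate config must be a list of definitions")
    return [
        AggregateDefinition(
            name=entry["name"],
            constituents=tuple(entry["constituents"]),
            exclusions=tuple(entry.get("exclusions", ())),
            reduction=entry.get("reduction", "mean"),
        )
        for entry in raw
    ]
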