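"""Leukocyte-fraction estimation from DNA methylation beta values.

The estimator assumes each tumor beta value is a two-component mixture of a
leukocyte level and a cancer-cell level:

    T_ik = B_k * f_ik + T_k * (1 - f_ik)   =>   f_ik = (T_ik - T_k) / (B_k - T_k)

where B_k is the mean beta of the leukocyte reference samples and T_k the
beta of the theoretically purest tumor (the minimum observed tumor beta for
leukocyte-high probes, the maximum for leukocyte-low probes).  Only probes
with an extreme leukocyte-tumor difference are used: probes are ranked by
(mean leukocyte beta - mean tumor beta) and the top and bottom ``n_top``
(default 1000 each) form the signature.  The per-sample fraction f_i is the
mode — the argmax of a Gaussian kernel density over [0, 1] — of the pooled
per-probe fractions f_ik.

Accuracy therefore rests on the anchor assumption that the cohort contains
a near-pure tumor sample; cohorts whose least-infiltrated sample still has
substantial immune content shrink all estimates toward zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "LeukocyteSignature",
    "build_leukocyte_signature",
    "probe_fractions",
    "leukocyte_fraction",
    "estimate_fractions",
]


@dataclass(frozen=True)
class LeukocyteSignature:
    """Extreme-probe signature with its per-probe anchors.

    high_probes / low_probes: leukocyte-high (L_h) and leukocyte-low (L_l)
    probe ids.  b / t: per retained probe, the leukocyte reference level B_k
    and the purest-tumor anchor T_k (indices are the union of both lists,
    minus probes dropped for B_k == T_k).
    """

    high_probes: tuple[str, ...]
    low_probes: tuple[str, ...]
    b: pd.Series
    t: pd.Series

    @property
    def probe_ids(self) -> pd.Index:
        return self.b.index


def build_leukocyte_signature(
    tumor: pd.DataFrame,
    leukocyte_ref: pd.DataFrame,
    n_top: int = 1000,
) -> LeukocyteSignature:
    """Select the 2 * n_top most leukocyte-discriminative probes and anchor them.

    Probes shared by both matrices are ranked by (mean leukocyte beta - mean
    tumor beta); ties are broken by probe id so the selection is
    deterministic.  Probes whose anchors coincide (B_k == T_k, undefined
    fraction) are dropped with a warning.
    """
    shared = tumor.index.intersection(leukocyte_ref.index)
    if len(shared) < 2 * n_top:
        raise ValueError(
            f"only {len(shared)} shared probes; need at least {2 * n_top}"
        )
    if tumor.shape[1] < 1 or leukocyte_ref.shape[1] < 1:
        raise ValueError("need at least one tumor and one leukocyte sample")
    tum = tumor.loc[shared]
    ref = leukocyte_ref.loc[shared]
    diff = (ref.mean(axis=1) - tum.mean(axis=1)).sort_index()
    order = diff.sort_values(kind="mergesort", ascending=False)
    high = order.index[:n_top]
    low = order.index[-n_top:]

    b = ref.mean(axis=1)
    t_high = tum.loc[high].min(axis=1)
    t_low = tum.loc[low].max(axis=1)
    probes = high.append(low)
    b = b.loc[probes]
    t = pd.concat([t_high, t_low])

    degenerate = probes[(b == t).to_numpy()]
    if len(degenerate):
        warnings.warn(
            f"dropping {len(degenerate)} probe(s) with B_k == T_k",
            stacklevel=2,
        )
        keep = ~probes.isin(degenerate)
        probes, b, t = probes[keep], b[keep], t[keep]
    return LeukocyteSignature(
        high_probes=tuple(h for h in high if h in set(probes)),
        low_probes=tuple(l for l in low if l in set(probes)),
        b=b,
        t=t,
    )


def probe_fractions(
    signature: LeukocyteSignature, tumor_column: pd.Series
) -> pd.Series:
    """Per-probe fractions f_ik = (T_ik - T_k) / (B_k - T_k) for one sample.

    Values outside [0, 1] are retained — they carry information about noise
    and are flagged downstream, not clipped.
    """
    missing = signature.probe_ids.difference(tumor_column.index)
    if len(missing):
        raise ValueError(
            f"tumor sample is missing {len(missing)} signature probe(s), "
            f"e.g. {list(missing[:3])}"
        )
    t_ik = tumor_column.loc[signature.probe_ids].astype(float)
    f = (t_ik - signature.t) / (signature.b - signature.t)
    f.name = "f_ik"
    return f


def leukocyte_fraction(
    f_ik: pd.Series | np.ndarray,
    min_probes: int = 50,
    grid_step: float = 0.001,
) -> float:
    """Mode-of-density aggregation of per-probe fractions.

    A Gaussian KDE (Silverman bandwidth) is fit to all finite f_ik and
    evaluated on a fixed grid over [0, 1]; the argmax is returned.  The
    search is restricted to [0, 1] because a leukocyte fraction is a
    physical proportion, although out-of-range f_ik still shape the
    density.  A zero-variance input short-circuits to the common value.
    """
    values = np.asarray(f_ik, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < min_probes:
        raise ValueError(
            f"only {len(values)} finite probe fractions; need >= {min_probes}"
        )
    if np.ptp(values) == 0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    return float(grid[np.argmax(kde(grid))])


def estimate_fractions(
    tumor: pd.DataFrame,
    leukocyte_ref: pd.DataFrame,
    n_top: int = 1000,
    min_probes: int = 50,
) -> pd.DataFrame:
    """Signature construction + per-sample fractions in one call.

    Returns one row per tumor sample: the estimate ``f``, the number of
    probes used, and the share of per-probe fractions falling outside
    [0, 1] (a diagnostic for noise / anchor violations).
    """
    signature = build_leukocyte_signature(tumor, leukocyte_ref, n_top=n_top)
    rows = []
    for sample in tumor.columns:
        f_ik = probe_fractions(signature, tumor[sample])
        rows.append(
            {
                "sample": sample,
                "f": leukocyte_fraction(f_ik, min_probes=min_probes),
                "n_probes_used": int(np.isfinite(f_ik).sum()),
                "frac_outside_unit": float(((f_ik < 0) | (f_ik > 1)).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("sample")
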