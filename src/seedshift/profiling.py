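"""TaqMan-style miRNA array profiling: global-mean normalization + Welch tests.

Input is a Ct matrix (PCR quantification cycles; lower Ct = more abundant),
miRNAs in rows, samples in columns, with each sample assigned to one of two
groups (e.g. osteoarthritic vs fracture-control cartilage).  Wells the
instrument could not call ("Undetermined") are *non-detects*: they are
flagged, and either imputed at the cycle ceiling (default 40, so that
miRNAs detected in only one group still yield finite statistics) or
excluded.

Normalization follows the global-mean method: within each sample,
dCt_i = Ct_i - mean(Ct over detected miRNAs of that sample), and relative
expression = 2^(-dCt).  Group comparisons use Welch's unequal-variance
t-test on the log2 scale (-dCt), since t-tests on 2^(-dCt) are distorted by
the exponential transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CtMatrix",
    "NormalizedExpression",
    "normalize_global_mean",
    "welch_t_test",
    "detection_filter",
    "differential_expression",
    "NON_DETECT_TOKENS",
]

NON_DETECT_TOKENS = {"undetermined", "na", "nan", "nd", ""}


@dataclass
class CtMatrix:
    """miRNA x sample Ct values with a non-detect mask and group labels.

    ``values`` holds floats with NaN at non-detects; ``detected`` is the
    boolean mask; ``groups`` maps sample -> group label (exactly two groups).
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    groups: pd.Series
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.detected.columns) or not self.values.index.equals(
            self.detected.index
        ):
            raise ValueError("values and detected mask must share index/columns")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        if len(self.group_names) != 2:
            raise ValueError(f"expected exactly 2 groups, got {list(self.group_names)}")
        vals = self.values.to_numpy(float)
        det = self.detected.to_numpy(bool)
        bad = det & ~((vals > 0) & (vals <= self.max_cycles))
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} detected Ct value(s) outside (0, {self.max_cycles}]"
            )

    @property
    def group_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def detection_rates(self) -> pd.DataFrame:
        """Per-miRNA detection rate in each group."""
        out = {}
        for g in self.group_names:
            cols = self.samples_in(g)
            out[g] = self.detected[cols].mean(axis=1)
        return pd.DataFrame(out)

    @classmethod
    def from_csv(
        cls,
        path: Union[str, Path],
        groups: Union[str, Path, pd.Series],
        max_cycles: float = 40.0,
    ) -> "CtMatrix":
        """Read a Ct CSV (rows = miRNA, cols = samples) + sample->group TSV.

        Non-numeric cells matching "Undetermined"/"NA"/"ND"/empty are parsed
        as non-detects.
        """
        raw = pd.read_csv(path, index_col=0, dtype=str)
        norm = raw.apply(lambda col: col.astype(str).str.strip())
        nondetect = norm.apply(lambda col: col.str.lower().isin(NON_DETECT_TOKENS))
        values = norm.mask(nondetect).apply(pd.to_numeric, errors="raise")
        if isinstance(groups, (str, Path)):
            gmap = pd.read_csv(groups, sep="\t", index_col=0).iloc[:, 0]
        else:
            gmap = groups
        return cls(values=values, detected=~nondetect, groups=gmap, max_cycles=max_cycles)

    def write_csv(self, path: Union[str, Path], nondetect_token: str = "Undetermined") -> None:
        out = self.values.map(lambda v: format(v, ".3f"))
        out = out.where(self.detected, nondetect_token)
        out.to_csv(path)


@dataclass
class NormalizedExpression:
    """Global-mean-normalized expression: dCt and 2^(-dCt) per well."""

    delta_ct: pd.DataFrame
    rel_expr: pd.DataFrame
    detected: pd.DataFrame
    groups: pd.Series
    dropped_samples: list[str] = field(default_factory=list)
    group_names: tuple[str, ...] = ()


def normalize_global_mean(
    ct: CtMatrix, nondetect: str = "impute", max_cycles: float | None = None
) -> NormalizedExpression:
    """Normalize each sample to the mean Ct of its detected miRNAs.

    ``nondetect="impute"`` substitutes the cycle ceiling (``max_cycles``,
    default the matrix's own) for non-detects before computing dCt (the
    detection flag is retained); ``"exclude"`` leaves them as NaN.  The
    per-sample mean is always taken over *detected* miRNAs only, so the
    normalization is invariant to adding a constant to a sample and the
    geometric mean of detected relative expressions within a sample is 1.
    Samples with fewer than 2 detections are dropped with a warning.
    """
    if nondetect not in ("impute", "exclude"):
        raise ValueError(f"nondetect must be 'impute' or 'exclude', got {nondetect!r}")
    ceiling = ct.max_cycles if max_cycles is None else max_cycles
    n_det = ct.detected.sum(axis=0)
    dropped = [s for s in ct.values.columns if n_det[s] < 2]
    if dropped:
        logger.warning("dropping sample(s) with < 2 detected miRNAs: %s", dropped)
    keep = [s for s in ct.values.columns if s not in dropped]
    values = ct.values[keep]
    detected = ct.detected[keep]
    filled = values.where(detected, other=ceiling) if nondetect == "impute" else values
    sample_mean = values.where(detected).mean(axis=0)  # detected wells only
    delta = filled.sub(sample_mean, axis=1)
    return NormalizedExpression(
        delta_ct=delta,
        rel_expr=2.0 ** (-delta),
        detected=detected,
        groups=ct.groups.loc[keep],
        dropped_samples=dropped,
        group_names=ct.group_names,
    )


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite (fractional) degrees
    of freedom and a two-sided p-value.  Two constant, equal groups give
    ``t = 0, p = 1``; constant groups with different means give ``p = 0``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need >= 2 values per group, got {a.size} and {b.size}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return sign * float("inf"), float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def detection_filter(ct: CtMatrix, min_rate: float) -> tuple[CtMatrix, pd.DataFrame]:
    """Drop miRNAs whose detection rate is below ``min_rate`` in BOTH groups.

    A miRNA detected mostly in one group (the disease-only pattern) is
    retained — such asymmetric detection is itself a finding.  Returns the
    filtered matrix and a per-miRNA report of group detection rates with a
    ``retained`` flag.
    """
    if not 0 <= min_rate <= 1:
        raise ValueError(f"min_rate must be in [0, 1], got {min_rate}")
    rates = ct.detection_rates()
    retained = (rates >= min_rate).any(axis=1) if min_rate > 0 else pd.Series(
        True, index=rates.index
    )
    report = rates.copy()
    report["retained"] = retained
    keep = retained[retained].index
    filtered = CtMatrix(
        values=ct.values.loc[keep],
        detected=ct.detected.loc[keep],
        groups=ct.groups,
        max_cycles=ct.max_cycles,
    )
    return filtered, report


def differential_expression(norm: NormalizedExpression) -> pd.DataFrame:
    """Per-miRNA Welch t-test between the two groups on the log2 scale.

    The tested quantity is -dCt (log2 relative expression); reported group
    means are on the relative-expression (2^-dCt) scale.  miRNAs without
    >= 2 usable values per group get NaN statistics.
    """
    g1, g2 = norm.group_names
    cols1 = [s for s in norm.delta_ct.columns if norm.groups[s] == g1]
    cols2 = [s for s in norm.delta_ct.columns if norm.groups[s] == g2]
    rows = []
    for mirna in norm.delta_ct.index:
        x1 = -norm.delta_ct.loc[mirna, cols1].to_numpy(float)
        x2 = -norm.delta_ct.loc[mirna, cols2].to_numpy(float)
        x1 = x1[np.isfinite(x1)]
        x2 = x2[np.isfinite(x2)]
        if x1.size >= 2 and x2.size >= 2:
            t, df, p = welch_t_test(x1, x2)
        else:
            t = df = p = float("nan")
        rows.append(
            {
                "mirna": mirna,
                f"mean_rel_{g1}": float(np.mean(2.0**x1)) if x1.size else float("nan"),
                f"mean_rel_{g2}": float(np.mean(2.0**x2)) if x2.size else float("nan"),
                f"det_rate_{g1}": float(norm.detected.loc[mirna, cols1].mean()),
                f"det_rate_{g2}": float(norm.detected.loc[mirna, cols2].mean()),
                "t": t,
                "df": df,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("mirna")
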