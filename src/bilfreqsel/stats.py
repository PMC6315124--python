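"""Supporting association statistics and qPCR absolute quantification.

Pearson correlation with a t-based two-sided p-value, one-way ANOVA across
allele groups, and the standard-curve arithmetic of absolute qPCR: copies
from mass via the ~650 g/mol/bp weight of double-stranded DNA, a Cq vs
log10(copies) regression line, and per-line expression traits as the mean of
log2 copy numbers over biological replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import InvalidParameterError, ValidationError

AVOGADRO = 6.02214076e23
DS_DNA_G_PER_MOL_PER_BP = 650.0


@dataclass
class CorrelationResult:
    r: float
    t: float
    p: float
    n: int


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return CorrelationResult(r, np.inf if r > 0 else -np.inf, 0.0, n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return CorrelationResult(r, float(t), float(p), n)


@dataclass
class AnovaResult:
    groups: list
    f: float
    p: float
    df_between: int
    df_within: int


def anova_one_way(values, group_labels) -> AnovaResult:
    """Classic one-way ANOVA (between/within sum-of-squares decomposition)."""
    values = np.asarray(values, float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValidationError("values and labels must have equal length")
    groups = list(dict.fromkeys(labels.tolist()))
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    n_total = values.size
    for g in groups:
        v = values[labels == g]
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += float(np.sum((v - v.mean()) ** 2))
    df_b = len(groups) - 1
    df_w = n_total - len(groups)
    if df_w < 1:
        raise ValidationError("no within-group degrees of freedom")
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(groups, float(f), p, df_b, df_w)


def copies_from_mass(concentration_ng_per_ul: float, fragment_length_bp: float) -> float:
    """Copies per microliter of a dsDNA fragment from its mass concentration."""
    if fragment_length_bp <= 0:
        raise InvalidParameterError("fragment length must be positive")
    if concentration_ng_per_ul < 0:
        raise InvalidParameterError("concentration must be nonnegative")
    grams = concentration_ng_per_ul * 1e-9
    return grams * AVOGADRO / (fragment_length_bp * DS_DNA_G_PER_MOL_PER_BP)


@dataclass
class StandardCurve:
    slope: float  # Cq per log10(copies); negative for valid curves
    intercept: float
    efficiency: float  # 10**(-1/slope) - 1
    r_squared: float

    def copies_from_cq(self, cq) -> np.ndarray | float:
        out = 10.0 ** ((np.asarray(cq, float) - self.intercept) / self.slope)
        return float(out) if out.ndim == 0 else out

    def cq_from_copies(self, copies) -> np.ndarray | float:
        out = self.intercept + self.slope * np.log10(np.asarray(copies, float))
        return float(out) if out.ndim == 0 else out


def fit_standard_curve(copies, cq) -> StandardCurve:
    """Least-squares line of Cq on log10(copies) from a dilution series."""
    copies = np.asarray(copies, float)
    cq = np.asarray(cq, float)
    if np.any(copies <= 0):
        raise InvalidParameterError("standard copies must be positive")
    if np.unique(copies).size < 3:
        raise InvalidParameterError("need at least 3 distinct copy levels")
    res = sps.linregress(np.log10(copies), cq)
    slope = float(res.slope)
    if slope >= 0:
        warnings.warn("standard-curve slope is nonnegative; efficiency meaningless")
        efficiency = np.nan
    else:
        efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(slope, float(res.intercept), float(efficiency), float(res.rvalue**2))


@dataclass
class QpcrQuantification:
    per_replicate: pd.DataFrame  # line_id, bio_rep, cq_mean, copies, log2_copies
    per_line: pd.Series  # mean log2 copies over biological replicates


def quantify_samples(curve: StandardCurve, cq_table: pd.DataFrame) -> QpcrQuantification:
    """Absolute quantification of Cq measurements against a standard curve.

    Technical replicates are averaged on the Cq scale before inversion to
    copies; the per-line trait is the mean of log2 copies over the available
    biological replicates.  Missing Cq values are skipped with a warning.
    """
    required = {"line_id", "bio_rep", "cq"}
    if not required.issubset(cq_table.columns):
        raise ValidationError(f"cq table needs columns {sorted(required)}")
    tab = cq_table.copy()
    n_missing = int(tab["cq"].isna().sum())
    if n_missing:
        warnings.warn(f"skipping {n_missing} missing Cq measurements")
        tab = tab.dropna(subset=["cq"])
    rows = []
    for (line, bio), sub in tab.groupby(["line_id", "bio_rep"], sort=False):
        cq_mean = float(sub["cq"].mean())
        copies = curve.copies_from_cq(cq_mean)
        rows.append((line, bio, cq_mean, copies, float(np.log2(copies))))
    per_rep = pd.DataFrame(
        rows, columns=["line_id", "bio_rep", "cq_mean", "copies", "log2_copies"]
    )
    dropped = set(cq_table["line_id"]) - set(per_rep["line_id"])
    if dropped:
        warnings.warn(f"samples dropped (all Cq missing): {sorted(dropped)[:5]}")
    per_line = per_rep.groupby("line_id", sort=False)["log2_copies"].mean()
    per_line.name = "log2_copies"
    return QpcrQuantification(per_rep, per_line)
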