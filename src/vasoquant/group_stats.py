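"""Group statistics: mean/SEM/t-CI summaries, one-way ANOVA with Tukey HSD,
and relative qPCR expression (2^-ddCt).

Per-arm endpoints (Df, MCA, biochemistry) are reported as mean ± SEM with a
Student-t 95% confidence interval (mean ∓ t_{1-α/2, n-1} × SEM); arms are
compared by classical one-way ANOVA followed by Tukey's honestly-significant
-difference test on the studentized-range distribution.

Relative expression uses the comparative-Ct method with amplification
efficiency fixed at 2: per sample, ΔCt = Ct_target − mean(reference Cts)
(averaging Cts of several reference genes equals the geometric mean of
their relative quantities); per group, fold change relative to control is
2^−(mean ΔCt_group − mean ΔCt_control).  The control group's own fold
change is exactly 1.

Displayed values round half-up to 2 decimals, matching the conventional
reporting precision; raw precision is retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .raster_io import InputError

#: Default gene roles for the expression analysis.
DEFAULT_TARGET_GENES = ("VEGF-A", "VEGF-R2")
DEFAULT_REFERENCE_GENES = ("B2M", "GAPDH")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), the display rounding rule."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GroupSummary:
    """Mean ± SEM with a Student-t confidence interval."""

    label: str
    n: int
    mean: float
    sem: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95

    def rounded(self, ndigits: int = 2) -> "GroupSummary":
        return GroupSummary(
            self.label, self.n,
            round_half_up(self.mean, ndigits), round_half_up(self.sem, ndigits + 1),
            round_half_up(self.ci_low, ndigits), round_half_up(self.ci_high, ndigits),
            self.confidence,
        )


@dataclass(frozen=True)
class TukeyPair:
    """One Tukey HSD pairwise comparison."""

    group_a: str
    group_b: str
    difference: float   # mean(a) - mean(b)
    p_adjusted: float


@dataclass
class ComparisonResult:
    """One-way ANOVA F/p plus Tukey HSD pairwise records."""

    f_statistic: float
    anova_p: float
    pairwise: list[TukeyPair]


def ci_from_summary(
    mean: float, sem: float, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Student-t CI from summary statistics: mean ∓ t_{1−α/2, n−1} × sem."""
    if n < 2:
        raise InputError(f"confidence interval undefined for n={n} (< 2)")
    if sem < 0:
        raise InputError(f"sem must be >= 0, got {sem}")
    t = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return mean - t * sem, mean + t * sem


def summarize_group(
    values, confidence: float = 0.95, label: str = ""
) -> GroupSummary:
    """Mean, SEM (= sd/sqrt(n), ddof=1) and t-based CI of one group."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise InputError(f"need a flat list of >= 2 values, got {v.size}")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    lo, hi = ci_from_summary(mean, sem, v.size, confidence)
    return GroupSummary(label, int(v.size), mean, sem, lo, hi, confidence)


def compare_groups(groups: dict[str, list | np.ndarray]) -> ComparisonResult:
    """One-way ANOVA across labelled groups, plus Tukey HSD post hoc.

    Degenerate input (all values identical overall) yields F = 0, p = 1 and
    all pairwise p = 1 by convention.
    """
    if len(groups) < 2:
        raise InputError(f"need >= 2 groups, got {len(groups)}")
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    for lab, arr in zip(labels, arrays):
        if arr.size < 2:
            raise InputError(f"group {lab!r} has n={arr.size} (< 2)")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        pairs = [
            TukeyPair(labels[i], labels[j], 0.0, 1.0)
            for i in range(len(labels)) for j in range(i + 1, len(labels))
        ]
        return ComparisonResult(0.0, 1.0, pairs)
    f_stat, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pairs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairs.append(
                TukeyPair(
                    labels[i], labels[j],
                    float(arrays[i].mean() - arrays[j].mean()),
                    float(hsd.pvalue[i, j]),
                )
            )
    return ComparisonResult(float(f_stat), float(p), pairs)


# ---------------------------------------------------------------------------
# relative qPCR expression


def validate_ct_table(
    table: pd.DataFrame,
    target_genes,
    reference_genes,
) -> None:
    """Check the (sample, group, gene, ct) table contract."""
    required = {"sample", "group", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(table["ct"].to_numpy(dtype=float)).all():
        raise InputError("Ct table contains non-finite ct values")
    refs = table[table["gene"].isin(reference_genes)]
    have_ref = set(refs["sample"])
    lacking = sorted(set(table["sample"]) - have_ref)
    if lacking:
        raise InputError(
            f"samples without any reference-gene measurement: {lacking}"
        )


def relative_expression(
    table: pd.DataFrame,
    control_group: str = "control",
    target_genes=DEFAULT_TARGET_GENES,
    reference_genes=DEFAULT_REFERENCE_GENES,
    method: str = "ddct",
) -> pd.DataFrame:
    """Per-group fold change of each target gene vs the control group.

    Returns a DataFrame with columns ``gene``, ``group``, ``fold_change``
    (2^−ΔΔCt) and ``mean_delta_ct``.  Several reference genes are combined
    by averaging their Cts per sample, which is the geometric mean of the
    corresponding relative quantities at efficiency 2.  The selection of
    reference genes is configurable (a single gene works the same way).
    """
    if method != "ddct":
        raise InputError(f"unknown method {method!r}; only 'ddct' is implemented")
    validate_ct_table(table, target_genes, reference_genes)
    if control_group not in set(table["group"]):
        raise InputError(f"control group {control_group!r} absent from table")

    ref = (
        table[table["gene"].isin(reference_genes)]
        .groupby("sample")["ct"].mean()
        .rename("ref_ct")
    )
    rows = []
    for gene in target_genes:
        sub = table[table["gene"] == gene]
        if sub.empty:
            continue
        merged = sub.merge(ref, on="sample")
        # duplicate wells of the same sample/gene average before ΔCt
        per_sample = merged.groupby(["sample", "group"], sort=False).agg(
            ct=("ct", "mean"), ref_ct=("ref_ct", "first")
        ).reset_index()
        per_sample["delta_ct"] = per_sample["ct"] - per_sample["ref_ct"]
        by_group = per_sample.groupby("group", sort=False)["delta_ct"].mean()
        if control_group not in by_group.index:
            raise InputError(
                f"control group {control_group!r} has no {gene} measurements"
            )
        control_dct = by_group[control_group]
        for group, dct in by_group.items():
            fold = 1.0 if group == control_group else float(2.0 ** -(dct - control_dct))
            rows.append(
                {"gene": gene, "group": group, "fold_change": fold,
                 "mean_delta_ct": float(dct)}
            )
    if not rows:
        raise InputError(f"no target-gene measurements found for {list(target_genes)}")
    return pd.DataFrame(rows)
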