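"""Expression quantification: FPKM heatmap transform, tissue calls,
stress/control ratios, and qPCR standard-curve relative expression.

The heatmap transform follows the usual cluster-display preparation:
every FPKM value is divided by the grand mean of the whole matrix and the
ratio is log2-transformed. qPCR quantification uses the standard-curve
method: each gene's dilution series (3-, 9-, 27-, 81-fold) is regressed
as Cq on log10(relative quantity); sample quantities are interpolated
from the gene's own curve, normalized to the reference gene, and
expressed relative to the control sample's mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_EXPRESSED_THRESHOLD = 1.0

RESPONSE_UP_EXTREME = "up_extreme"
RESPONSE_UP = "up"
RESPONSE_DOWN = "down"
RESPONSE_NO_CHANGE = "no_change"


def heatmap_transform(matrix: pd.DataFrame,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """log2((x + pc) / grand mean of (x + pc)) over the whole matrix.

    The grand (not per-gene) mean preserves tissue-to-tissue contrasts;
    with pseudocount 0 the mean of 2^output over all cells is exactly 1.
    """
    values = matrix.to_numpy(dtype=float) + pseudocount
    if (values < 0).any():
        raise ValueError("negative FPKM values")
    grand_mean = values.mean()
    if grand_mean == 0:
        raise ValueError("all-zero matrix with zero pseudocount")
    return pd.DataFrame(np.log2(values / grand_mean),
                        index=matrix.index, columns=matrix.columns)


def tissue_calls(matrix: pd.DataFrame,
                 threshold: float = DEFAULT_EXPRESSED_THRESHOLD):
    """Boolean expressed matrix plus the genes expressed in no sample."""
    expressed = matrix >= threshold
    never = [g for g in matrix.index if not expressed.loc[g].any()]
    return expressed, never


def stress_ratio(stress: pd.DataFrame, control: pd.DataFrame,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """(stress + pc) / (control + pc), elementwise."""
    if stress.shape != control.shape:
        raise ValueError("stress and control matrices differ in shape")
    return (stress + pseudocount) / (control.to_numpy() + pseudocount)


# ---------------------------------------------------------------------------
# qPCR standard-curve quantification


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency_pct(self) -> float:
        """Amplification efficiency: (10^(−1/slope) − 1) × 100."""
        if self.slope == 0:
            raise ZeroDivisionError("flat dilution series: slope 0 has no efficiency")
        return (10 ** (-1.0 / self.slope) - 1.0) * 100.0

    def quantity(self, cq) -> float:
        """Interpolate a relative quantity from a Cq value."""
        return 10 ** ((np.asarray(cq, dtype=float) - self.intercept) / self.slope)


def fit_standard_curve(dilution_factors, cq_values) -> StandardCurve:
    """Least-squares fit of Cq on log10(1 / dilution).

    A perfect-doubling chemistry loses one cycle per 2-fold dilution, so
    a 10-fold change in quantity spans log2(10) = 3.3219 cycles and the
    slope is −3.3219 at 100% efficiency.
    """
    x = np.log10(1.0 / np.asarray(dilution_factors, dtype=float))
    y = np.asarray(cq_values, dtype=float)
    if len(x) < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in dilution factors")
    fit = stats.linregress(x, y)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue ** 2))


@dataclass
class RelativeExpression:
    gene: str
    condition: str
    timepoint: str
    fold_change_mean: float
    fold_change_sd: float
    n_bio: int
    n_tech: int


def relative_expression(
    target_cq: pd.DataFrame,
    ref_cq: pd.DataFrame,
    target_curve: StandardCurve,
    ref_curve: StandardCurve,
    control_sample: str,
    gene: str = "",
) -> list[RelativeExpression]:
    """Standard-curve relative expression, mean ± SD over biological replicates.

    Both Cq tables need columns (condition, timepoint, bio_rep, tech_rep,
    cq) and matching replicate structure. Per well, quantity is read off
    the gene's own curve; the target quantity is normalized by the
    reference gene's, technical replicates are averaged within each
    biological replicate, every normalized quantity is divided by the
    control sample's mean, and the mean and SD over biological replicates
    are reported. ``control_sample`` names a (condition, timepoint) pair
    as "condition:timepoint" or just a timepoint applied per condition.
    """
    required = {"condition", "timepoint", "bio_rep", "tech_rep", "cq"}
    for name, df in (("target", target_cq), ("reference", ref_cq)):
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{name} Cq table missing columns {sorted(missing)}")

    merged = target_cq.merge(
        ref_cq, on=["condition", "timepoint", "bio_rep", "tech_rep"],
        suffixes=("_target", "_ref"),
    )
    if len(merged) < len(target_cq):
        warnings.warn("reference wells missing for some target wells; "
                      "computing over the matched subset")
    merged["norm_q"] = (
        target_curve.quantity(merged["cq_target"])
        / ref_curve.quantity(merged["cq_ref"])
    )
    # average technical replicates within each biological replicate
    bio = (
        merged.groupby(["condition", "timepoint", "bio_rep"], as_index=False)
        .agg(norm_q=("norm_q", "mean"), n_tech=("norm_q", "size"))
    )

    if ":" in control_sample:
        ctrl_cond, ctrl_tp = control_sample.split(":", 1)
        ctrl_mask = (bio.condition == ctrl_cond) & (bio.timepoint == ctrl_tp)
    else:
        ctrl_mask = bio.timepoint == control_sample

    results = []
    for (cond, tp), group in bio.groupby(["condition", "timepoint"]):
        if ":" in control_sample:
            ctrl = bio[ctrl_mask]
        else:
            ctrl = bio[(bio.condition == cond) & ctrl_mask]
        if ctrl.empty:
            warnings.warn(f"no control wells for condition {cond!r}; skipped")
            continue
        baseline = ctrl.norm_q.mean()
        folds = group.norm_q / baseline
        results.append(
            RelativeExpression(
                gene=gene, condition=cond, timepoint=tp,
                fold_change_mean=float(folds.mean()),
                fold_change_sd=float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
                n_bio=len(folds), n_tech=int(group.n_tech.max()),
            )
        )
    return results


def classify_response(
    fold_changes,
    extreme_fold: float = 100.0,
    up_fold: float = 2.0,
    down_fold: float = 0.5,
) -> str:
    """Response class from the fold changes across stress timepoints."""
    folds = [float(f) for f in fold_changes]
    if not folds:
        return RESPONSE_NO_CHANGE
    if max(folds) > extreme_fold:
        return RESPONSE_UP_EXTREME
    if max(folds) >= up_fold:
        return RESPONSE_UP
    if min(folds) <= down_fold:
        return RESPONSE_DOWN
    return RESPONSE_NO_CHANGE


def quantify_qpcr_table(
    cq_table: pd.DataFrame,
    reference_gene: str,
    control_sample: str,
) -> pd.DataFrame:
    """End-to-end qPCR analysis of a long-format Cq table.

    Expects columns (gene, condition, timepoint, bio_rep, tech_rep, cq,
    standard) where ``standard`` is the dilution factor for curve wells
    (3/9/27/81) and NA/0 for biological samples. Returns the fold-change
    table with per-gene curve statistics and response classes; genes
    without sample wells yield NA rows.
    """
    std = cq_table[cq_table["standard"].fillna(0) > 0]
    samples = cq_table[cq_table["standard"].fillna(0) == 0]
    curves = {}
    for gene, group in std.groupby("gene"):
        curves[gene] = fit_standard_curve(group["standard"], group["cq"])
    if reference_gene not in curves:
        raise ValueError(f"no dilution series for reference gene {reference_gene!r}")
    ref_rows = samples[samples.gene == reference_gene]

    records = []
    for gene in sorted(set(cq_table.gene) - {reference_gene}):
        gene_rows = samples[samples.gene == gene]
        if gene_rows.empty or gene not in curves:
            records.append({"gene": gene, "condition": pd.NA, "timepoint": pd.NA,
                            "fold_change_mean": np.nan, "fold_change_sd": np.nan,
                            "n_bio": 0, "n_tech": 0, "response_class": pd.NA,
                            "curve_slope": np.nan, "curve_efficiency_pct": np.nan})
            continue
        curve = curves[gene]
        rels = relative_expression(gene_rows, ref_rows, curve, curves[reference_gene],
                                   control_sample, gene=gene)
        ctrl_tp = control_sample.split(":", 1)[-1]
        for r in rels:
            stress_folds = [x.fold_change_mean for x in rels
                            if x.condition == r.condition and x.timepoint != ctrl_tp]
            records.append({
                "gene": gene, "condition": r.condition, "timepoint": r.timepoint,
                "fold_change_mean": r.fold_change_mean,
                "fold_change_sd": r.fold_change_sd,
                "n_bio": r.n_bio, "n_tech": r.n_tech,
                "response_class": classify_response(stress_folds),
                "curve_slope": curve.slope,
                "curve_efficiency_pct": curve.efficiency_pct,
            })
    return pd.DataFrame.from_records(records)
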