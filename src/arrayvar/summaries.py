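"""Across-gene summaries of the variance decomposition.

Reproduces the study's result surfaces: correlations between replicate
hybridisations at each level of the hierarchy, distributions of per-
component standard deviations and the proportion of variance each
component contributes, the biological (subject + day) versus technical
(stimulation tube + amplification + residual) aggregation, ranking of
genes by a chosen component, the sex-versus-LPS fixed-effect comparison,
monocyte-proportion summaries and the comparison of the LPS effect with
every variability component on a common log2 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ArrayDesign, COMPONENTS
from .preprocess import ExpressionMatrix
from .varcomp import BIOLOGICAL, TECHNICAL, VarCompFit, test_lps_effect

__all__ = [
    "ComponentSummary",
    "replicate_correlations",
    "summarize_components",
    "rank_genes_by_component",
    "sex_vs_lps",
    "monocyte_summaries",
    "effect_vs_variability",
    "plot_component_boxplots",
]

#: Replication levels for the correlation matrix, innermost outward.
CORRELATION_LEVELS = ("hyb", "amp", "stim", "day", "subject")


def _boxstats(values: np.ndarray) -> dict:
    """Tukey box-plot statistics: quartiles, 1.5*IQR whiskers, outliers."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo) & (v <= hi)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()) if inside.size else float(med),
        "whisker_high": float(inside.max()) if inside.size else float(med),
        "n_outliers": int(((v < lo) | (v > hi)).sum()),
    }


@dataclass
class ComponentSummary:
    """Across-gene distribution of each component's SD plus aggregates.

    ``proportion_of_variance`` uses the across-gene mean sigma2 per
    component over the total mean, so the proportions sum to one exactly.
    The biological/technical aggregates sum member variances per gene
    before taking the square root.
    """

    component_stats: dict[str, dict]
    proportion_of_variance: dict[str, float]
    biological: dict
    technical: dict
    n_genes: int

    def frame(self) -> pd.DataFrame:
        rows = []
        for comp, st in self.component_stats.items():
            rows.append(
                {"component": comp, "proportion": self.proportion_of_variance[comp], **st}
            )
        rows.append({"component": "biological", "proportion": np.nan, **self.biological})
        rows.append({"component": "technical", "proportion": np.nan, **self.technical})
        return pd.DataFrame(rows)


def summarize_components(fits: Sequence[VarCompFit]) -> ComponentSummary:
    """Summarize per-gene variance components across genes."""
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to summarize")
    comps = [c for c in COMPONENTS if c in fits[0].sigma2]
    sig = {c: np.array([f.sigma2.get(c, 0.0) for f in fits]) for c in comps}
    means = {c: float(sig[c].mean()) for c in comps}
    total = sum(means.values())
    if total > 0:
        prop = {c: means[c] / total for c in comps}
    else:
        prop = {c: 0.0 for c in comps}
    stats = {c: _boxstats(np.sqrt(sig[c])) for c in comps}
    zero = np.zeros(len(fits))
    bio = np.sqrt(sum((sig[c] for c in BIOLOGICAL if c in sig), zero))
    tech = np.sqrt(sum((sig[c] for c in TECHNICAL if c in sig), zero))
    return ComponentSummary(
        component_stats=stats,
        proportion_of_variance=prop,
        biological=_boxstats(bio),
        technical=_boxstats(tech),
        n_genes=len(fits),
    )


# ---------------------------------------------------------------------------
# Replicate correlations (scatter-matrix summary)
# ---------------------------------------------------------------------------

def _find_array(design, **fixed):
    for a in design:
        if all(getattr(a, k) == v for k, v in fixed.items()):
            return a
    return None


def replicate_correlations(
    matrix: ExpressionMatrix | pd.DataFrame,
    design: Sequence[ArrayDesign],
    *,
    comparator_subject: str | None = None,
    levels: Sequence[str] = CORRELATION_LEVELS,
) -> dict[str, list[float]]:
    """Pearson correlations between replicate arrays at each level.

    For each subject carrying hybridisation replicates, the index array is
    the (day 1, tube 1, amp 1, hyb 1) stimulated hybridisation; it is
    compared against its repeat hybridisations (``hyb``), the repeat
    amplification (``amp``), the parallel stimulation tube (``stim``), the
    same sample on the other day (``day``) and the matching array of a
    comparator subject (``subject``; by default the next subject in the
    design).  Correlations are computed across genes on the filtered
    matrix.  Levels with no available pair are omitted with a warning.
    """
    M = matrix.matrix() if isinstance(matrix, ExpressionMatrix) else matrix
    by_id = {a.array_id: a for a in design}
    missing_cols = [a for a in by_id if a not in M.columns]
    if missing_cols:
        raise ValueError(f"matrix lacks arrays: {missing_cols}")

    rep_subjects = sorted(
        {a.subject for a in design if a.lps == 1 and a.hyb_rep > 1}
    )
    if not rep_subjects:
        rep_subjects = sorted({a.subject for a in design})[:1]
    subjects = sorted({a.subject for a in design})

    out: dict[str, list[float]] = {lvl: [] for lvl in levels}
    for subj in rep_subjects:
        index = _find_array(
            design, subject=subj, day=1, lps=1, stim_tube=1, amp_run=1, hyb_rep=1
        )
        if index is None:
            continue
        others = [s for s in subjects if s != subj]
        comp_subj = comparator_subject or (others[0] if others else None)
        partners = {
            "hyb": [
                a for a in design
                if a.subject == subj and a.day == 1 and a.lps == 1
                and a.stim_tube == 1 and a.amp_run == 1 and a.hyb_rep > 1
            ],
            "amp": [
                a for a in design
                if a.subject == subj and a.day == 1 and a.lps == 1
                and a.stim_tube == 1 and a.amp_run > 1 and a.hyb_rep == 1
            ],
            "stim": [
                a for a in design
                if a.subject == subj and a.day == 1 and a.lps == 1
                and a.stim_tube == 2 and a.amp_run == 1 and a.hyb_rep == 1
            ],
            "day": [
                a for a in design
                if a.subject == subj and a.day == 2 and a.lps == 1
                and a.stim_tube == 1 and a.amp_run == 1 and a.hyb_rep == 1
            ],
            "subject": [
                a for a in design
                if comp_subj is not None and a.subject == comp_subj and a.day == 1
                and a.lps == 1 and a.stim_tube == 1 and a.amp_run == 1 and a.hyb_rep == 1
            ],
        }
        x = M[index.array_id].to_numpy()
        for lvl in levels:
            for partner in partners.get(lvl, []):
                y = M[partner.array_id].to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    continue
                out[lvl].append(float(np.corrcoef(x, y)[0, 1]))
    for lvl in list(out):
        if not out[lvl]:
            warnings.warn(f"no replicate pair available at level '{lvl}'; omitted")
            del out[lvl]
    return out


# ---------------------------------------------------------------------------
# Gene ranking and fixed-effect comparisons
# ---------------------------------------------------------------------------

def rank_genes_by_component(
    fits: Sequence[VarCompFit], component: str, top_n: int = 10
) -> pd.DataFrame:
    """Rank genes by the SD of one variance component, descending.

    Ties break by gene_id; ``top_n`` larger than the gene count returns
    all genes.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component: {component}")
    if fits and component not in fits[0].sigma2:
        raise ValueError(f"component '{component}' was not fitted")
    frame = pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "sd": [f.sd(component) for f in fits],
        }
    ).sort_values(["sd", "gene_id"], ascending=[False, True], kind="mergesort")
    return frame.head(max(int(top_n), 0)).reset_index(drop=True)


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = x.std() or 1.0
    return (x - med) / scale


def sex_vs_lps(
    fits: Sequence[VarCompFit], z_threshold: float = 4.0
) -> pd.DataFrame:
    """Per-gene sex effect against LPS effect, with robust outlier flags.

    Flags a gene on an axis when its robust z-score (median/MAD) exceeds
    ``z_threshold`` in absolute value; sex-specific genes (XIST-like)
    should flag on the sex axis only.
    """
    sex = np.array([f.beta.get("sex", 0.0) for f in fits])
    lps = np.array([f.beta.get("lps", 0.0) for f in fits])
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "sex_effect": sex,
            "lps_effect": lps,
            "sex_outlier": np.abs(_robust_z(sex)) > z_threshold,
            "lps_outlier": np.abs(_robust_z(lps)) > z_threshold,
        }
    )


# ---------------------------------------------------------------------------
# Monocyte proportions
# ---------------------------------------------------------------------------

def monocyte_summaries(table: pd.DataFrame) -> dict:
    """Between-day and between-subject spread of monocyte percentages.

    For each timepoint: the maximum over subjects of the absolute
    between-day difference (with the subject attaining it) and the
    between-subject min/max range per day.
    """
    required = {"subject", "day", "timepoint", "percent"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    wide = table.pivot_table(
        index=["subject", "timepoint"], columns="day", values="percent"
    )
    if wide.isna().any().any():
        raise ValueError("incomplete table: missing subject/day/timepoint cells")
    out: dict = {"between_day": {}, "between_subject": {}}
    for tp, grp in wide.groupby(level="timepoint"):
        diff = (grp[1] - grp[2]).abs()
        subj = diff.idxmax()[0]
        out["between_day"][tp] = {
            "max_difference": float(round(diff.max(), 10)),
            "subject": subj,
        }
    for (day, tp), grp in table.groupby(["day", "timepoint"]):
        out["between_subject"][f"day{day}_{tp}"] = {
            "min": float(grp["percent"].min()),
            "max": float(grp["percent"].max()),
            "range": float(round(grp["percent"].max() - grp["percent"].min(), 10)),
        }
    return out


# ---------------------------------------------------------------------------
# LPS effect vs variability on a common scale
# ---------------------------------------------------------------------------

def effect_vs_variability(
    fits: Sequence[VarCompFit],
    *,
    de_table: pd.DataFrame | None = None,
    fdr: float = 0.05,
) -> dict:
    """Compare |LPS effect| among significant genes with component SDs.

    Returns box statistics of the absolute LPS fixed effect over genes
    significant at ``fdr`` alongside each component's SD distribution, all
    on the log2 scale, plus the ratio of the median significant |effect|
    to the largest component median SD.  Degenerate cases (no significant
    genes, or all components zero) are flagged and the ratio reported as
    not applicable (None).
    """
    if de_table is None:
        de_table = test_lps_effect(fits, fdr=fdr)
    sig_ids = set(de_table.loc[de_table["significant"], "gene_id"])
    comps = [c for c in COMPONENTS if fits and c in fits[0].sigma2]
    comp_stats = {
        c: _boxstats(np.array([f.sd(c) for f in fits])) for c in comps
    }
    comp_medians = {c: comp_stats[c]["median"] for c in comps}
    max_comp_median = max(comp_medians.values()) if comp_medians else 0.0
    sig_effects = np.array(
        [abs(f.beta.get("lps", 0.0)) for f in fits if f.gene_id in sig_ids]
    )
    result: dict = {
        "n_significant": int(len(sig_effects)),
        "component_sd": comp_stats,
        "lps_effect_abs": _boxstats(sig_effects) if sig_effects.size else None,
        "degenerate": False,
        "ratio_median_effect_to_max_component_sd": None,
    }
    if sig_effects.size == 0 or max_comp_median == 0:
        result["degenerate"] = True
        return result
    result["ratio_median_effect_to_max_component_sd"] = float(
        np.median(sig_effects) / max_comp_median
    )
    return result


def plot_component_boxplots(summary: ComponentSummary, path) -> None:
    """Box plot of per-component SD distributions (optional artefact)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = list(summary.component_stats)
    fig, ax = plt.subplots(figsize=(8, 4))
    boxes = []
    for c in comps:
        st = summary.component_stats[c]
        boxes.append(
            {
                "med": st["median"],
                "q1": st["q1"],
                "q3": st["q3"],
                "whislo": st["whisker_low"],
                "whishi": st["whisker_high"],
                "fliers": [],
                "label": c,
            }
        )
    ax.bxp(boxes, showfliers=False)
    ax.set_ylabel("SD (log2 scale)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
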