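"""Spot-level preprocessing for two-colour arrays.

Converts per-array spot tables (foreground/background per channel on a
print-tip grid) into a filtered matrix of normalized log-ratios:

1. background correction with a small positive offset so no log-ratio is
   missing;
2. print-tip loess normalization of M on A, fitted only on probes whose
   mean A-value clears an intensity threshold;
3. removal of control probes and of the fraction of library probes with
   lowest mean A (transcripts not expressed in the tissue).

M is log2(sample/reference) and A the average log2 intensity of the two
channels.  The sample is carried on Cy5 (635 nm) and the common reference
on Cy3 (532 nm); no dye-swap support.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

logger = logging.getLogger(__name__)

__all__ = [
    "SPOT_COLUMNS",
    "ExpressionMatrix",
    "read_gpr",
    "write_gpr",
    "background_correct",
    "spot_m_a",
    "printtip_loess_normalize",
    "build_expression_matrix",
    "filter_probes",
]

#: Canonical spot-table columns (internal naming).
SPOT_COLUMNS = [
    "probe_id",
    "is_control",
    "block",
    "row",
    "column",
    "FG_sample",
    "BG_sample",
    "FG_ref",
    "BG_ref",
]

# GPR-dialect column names (subset of the GenePix standard; 635 = Cy5
# sample channel, 532 = Cy3 reference channel).
_GPR_MAP = {
    "Block": "block",
    "Row": "row",
    "Column": "column",
    "ID": "probe_id",
    "F635 Median": "FG_sample",
    "B635 Median": "BG_sample",
    "F532 Median": "FG_ref",
    "B532 Median": "BG_ref",
}
CONTROL_PREFIX = "CTRL"


@dataclass
class ExpressionMatrix:
    """Genes x arrays matrix of normalized log2 ratios with filter state.

    ``M`` holds probe x array log-ratios, ``A`` the per-probe mean log2
    intensity across arrays (the filtering statistic), ``A_within`` the
    within-array A-values used by the loess fit.  ``filter_mask`` marks
    retained probes; ``matrix()`` returns the filtered view.
    """

    M: pd.DataFrame
    A: pd.Series
    A_within: pd.DataFrame | None = None
    is_control: pd.Series | None = None
    filter_mask: pd.Series | None = None
    normalization_audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_control is None:
            self.is_control = pd.Series(False, index=self.M.index)
        if self.filter_mask is None:
            self.filter_mask = pd.Series(True, index=self.M.index)

    @property
    def n_genes(self) -> int:
        return int(self.filter_mask.sum())

    @property
    def array_ids(self) -> list[str]:
        return list(self.M.columns)

    def matrix(self) -> pd.DataFrame:
        return self.M.loc[self.filter_mask]

    def write(self, path_prefix: str) -> None:
        self.matrix().to_csv(f"{path_prefix}_M.tsv", sep="\t")
        self.A.loc[self.filter_mask].rename("A").to_csv(f"{path_prefix}_A.tsv", sep="\t")
        with open(f"{path_prefix}_audit.json", "w") as fh:
            json.dump(self.normalization_audit, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# GPR-dialect I/O
# ---------------------------------------------------------------------------

def write_gpr(spots: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    """Write a spot table in the tab-delimited GPR-like dialect."""
    out = pd.DataFrame(
        {
            "Block": spots["block"],
            "Row": spots["row"],
            "Column": spots["column"],
            "ID": spots["probe_id"],
            "Flags": 0,
            "F635 Median": spots["FG_sample"],
            "B635 Median": spots["BG_sample"],
            "F532 Median": spots["FG_ref"],
            "B532 Median": spots["BG_ref"],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_gpr(path) -> pd.DataFrame:
    """Parse a GPR-like spot file into the canonical spot-table layout.

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
    else:
        raise ValueError(f"{path}: no data rows (header-only file)")
    header = lines[body_start].rstrip("\n").split("\t")
    missing = [c for c in _GPR_MAP if c not in header]
    if missing:
        raise ValueError(
            f"{path}, line {body_start + 1}: missing required columns {missing}"
        )
    idx = {c: header.index(c) for c in _GPR_MAP}
    rows = []
    for ln, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ValueError(
                f"{path}, line {ln}: expected {len(header)} fields, got {len(parts)}"
            )
        try:
            rows.append(
                {
                    "block": int(parts[idx["Block"]]),
                    "row": int(parts[idx["Row"]]),
                    "column": int(parts[idx["Column"]]),
                    "probe_id": parts[idx["ID"]],
                    "FG_sample": float(parts[idx["F635 Median"]]),
                    "BG_sample": float(parts[idx["B635 Median"]]),
                    "FG_ref": float(parts[idx["F532 Median"]]),
                    "BG_ref": float(parts[idx["B532 Median"]]),
                }
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {ln}: {exc}") from None
    spots = pd.DataFrame(rows)
    spots["is_control"] = spots["probe_id"].str.startswith(CONTROL_PREFIX)
    dup = spots.duplicated(subset=["block", "row", "column"])
    if dup.any():
        raise ValueError(f"{path}: duplicate grid coordinates at rows {list(spots.index[dup])}")
    return spots[SPOT_COLUMNS]


# ---------------------------------------------------------------------------
# Background correction
# ---------------------------------------------------------------------------

def background_correct(
    spots: pd.DataFrame, offset: float = 50.0, floor: float | None = None
) -> pd.DataFrame:
    """Background-subtract both channels and add a stabilising offset.

    corrected = FG - BG + offset, per channel.  With the default offset of
    50 any spot with FG - BG > -50 stays positive, so log-ratios remain
    finite and low-intensity ratios are damped toward zero.  Spots that are
    still non-positive (possible with offset 0) are flagged ``missing``
    rather than dropped.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    out = spots.copy()
    for ch in ("sample", "ref"):
        corr = out[f"FG_{ch}"] - out[f"BG_{ch}"] + offset
        if floor is not None:
            corr = corr.clip(lower=floor)
        out[f"corr_{ch}"] = corr
    out["missing"] = (out["corr_sample"] <= 0) | (out["corr_ref"] <= 0)
    return out


def spot_m_a(corrected: pd.DataFrame) -> pd.DataFrame:
    """Attach M and within-array A computed from corrected intensities."""
    out = corrected.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ls = np.log2(out["corr_sample"].to_numpy())
        lr = np.log2(out["corr_ref"].to_numpy())
    out["M"] = np.where(out["missing"], np.nan, ls - lr)
    out["A"] = np.where(out["missing"], np.nan, 0.5 * (ls + lr))
    return out


# ---------------------------------------------------------------------------
# Print-tip loess normalization
# ---------------------------------------------------------------------------

def printtip_loess_normalize(
    m: np.ndarray,
    a: np.ndarray,
    block: np.ndarray,
    eligible: np.ndarray,
    *,
    span: float = 0.4,
    robust_iterations: int = 1,
    min_fit_points: int = 10,
) -> tuple[np.ndarray, dict]:
    """Normalize one array's M-values by a per-print-tip loess of M on A.

    Within each print-tip block a locally weighted linear regression of M on
    A (tricube distance weights; ``span`` is the fraction of fit-eligible
    points in each local window; ``robust_iterations`` bisquare
    re-weighting passes) is fitted using only ``eligible`` probes —
    library probes whose mean A clears the intensity threshold — and the
    fitted trend, linearly interpolated in A, is subtracted from every
    probe in the block.  Blocks with fewer eligible probes than
    ``min_fit_points`` fall back to median-centering with a warning.

    Returns the normalized M and a per-block audit record.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    out = m.copy()
    audit: dict = {"span": span, "robust_iterations": robust_iterations, "blocks": {}}
    for b in np.unique(block):
        in_block = block == b
        fit_mask = in_block & eligible & np.isfinite(m) & np.isfinite(a)
        n_fit = int(fit_mask.sum())
        if n_fit < min_fit_points:
            med = float(np.nanmedian(m[fit_mask])) if n_fit else 0.0
            out[in_block] = m[in_block] - med
            audit["blocks"][int(b)] = {"method": "median", "n_fit": n_fit, "shift": med}
            logger.warning(
                "print-tip block %s has %d eligible probes (<%d); median-centered",
                b, n_fit, min_fit_points,
            )
            continue
        fitted = _sm_lowess(
            m[fit_mask],
            a[fit_mask],
            frac=span,
            it=robust_iterations,
            return_sorted=True,
        )
        xs, ys = fitted[:, 0], fitted[:, 1]
        # collapse duplicate abscissae for interpolation
        xs_u, inv = np.unique(xs, return_index=True)
        trend = np.interp(a[in_block], xs_u, ys[inv])
        out[in_block] = m[in_block] - trend
        audit["blocks"][int(b)] = {"method": "loess", "n_fit": n_fit}
    return out, audit


# ---------------------------------------------------------------------------
# Matrix assembly and filtering
# ---------------------------------------------------------------------------

def build_expression_matrix(
    spot_tables: Mapping[str, pd.DataFrame],
    *,
    offset: float = 50.0,
    span: float = 0.4,
    a_threshold: float = 6.5,
    robust_iterations: int = 1,
    min_fit_points: int = 10,
    normalize: bool = True,
) -> ExpressionMatrix:
    """Run background correction and print-tip loess over a set of arrays.

    ``spot_tables`` maps array_id to a spot table; probe sets must agree
    across arrays.  Eligibility for the loess fit uses each probe's mean
    A-value across all arrays (zero weight below ``a_threshold``) and
    excludes control probes; the fitted trend is still subtracted from
    every probe.
    """
    if not spot_tables:
        raise ValueError("no spot tables supplied")
    per_array = {}
    ref_probes = None
    for aid, spots in spot_tables.items():
        ma = spot_m_a(background_correct(spots, offset=offset))
        ma = ma.sort_values(["block", "row", "column"]).reset_index(drop=True)
        if ref_probes is None:
            ref_probes = ma["probe_id"]
        elif not ref_probes.equals(ma["probe_id"]):
            raise ValueError(f"array {aid}: probe layout differs from first array")
        per_array[aid] = ma

    probe_ids = ref_probes.to_numpy()
    arrays = list(per_array)
    M = np.column_stack([per_array[aid]["M"].to_numpy() for aid in arrays])
    A = np.column_stack([per_array[aid]["A"].to_numpy() for aid in arrays])
    is_control = per_array[arrays[0]]["is_control"].to_numpy()
    block = per_array[arrays[0]]["block"].to_numpy()
    mean_a = np.nanmean(A, axis=1)

    audit: dict = {"offset": offset, "a_threshold": a_threshold, "per_array": {}}
    if normalize:
        eligible = (mean_a >= a_threshold) & ~is_control
        for j, aid in enumerate(arrays):
            M[:, j], rec = printtip_loess_normalize(
                M[:, j], A[:, j], block, eligible,
                span=span,
                robust_iterations=robust_iterations,
                min_fit_points=min_fit_points,
            )
            audit["per_array"][aid] = rec

    # aggregate duplicate probe ids (multiple spots per probe) by mean
    mdf = pd.DataFrame(M, columns=arrays)
    mdf["probe_id"] = probe_ids
    adf = pd.DataFrame(A, columns=arrays)
    adf["probe_id"] = probe_ids
    ctrl = pd.Series(is_control, index=probe_ids).groupby(level=0).any()
    Mg = mdf.groupby("probe_id").mean()
    Ag = adf.groupby("probe_id").mean()
    mean_a_g = Ag.mean(axis=1)

    return ExpressionMatrix(
        M=Mg,
        A=mean_a_g.rename("A"),
        A_within=Ag,
        is_control=ctrl.reindex(Mg.index),
        normalization_audit=audit,
    )


def filter_probes(
    matrix: ExpressionMatrix,
    *,
    control_removal: bool = True,
    low_expr_fraction: float = 0.33,
) -> ExpressionMatrix:
    """Flag control probes and the lowest-intensity library probes.

    Controls are removed first; then the ``low_expr_fraction`` of remaining
    library probes with the lowest mean A-values is dropped, modelling
    transcripts not expressed in the sampled tissue.  The retained count is
    ``round((1 - fraction) * n_library)`` (round-half-even); ties on A are
    broken by probe_id order, so the cut is deterministic.
    """
    if not (0 <= low_expr_fraction < 1):
        raise ValueError("low_expr_fraction must be in [0, 1)")
    mask = pd.Series(True, index=matrix.M.index)
    if control_removal:
        mask &= ~matrix.is_control
    library = matrix.A.loc[mask]
    n_keep = int(np.round((1.0 - low_expr_fraction) * len(library)))
    order = (
        pd.DataFrame({"A": library})
        .reset_index(names="probe_id")
        .sort_values(["A", "probe_id"], ascending=[False, True], kind="mergesort")
    )
    keep_ids = set(order["probe_id"].iloc[:n_keep])
    mask &= pd.Series(matrix.M.index.isin(keep_ids), index=matrix.M.index)
    audit = dict(matrix.normalization_audit)
    audit["filter"] = {
        "control_removal": control_removal,
        "low_expr_fraction": low_expr_fraction,
        "n_library": int(len(library)),
        "n_retained": int(n_keep),
    }
    return ExpressionMatrix(
        M=matrix.M,
        A=matrix.A,
        A_within=matrix.A_within,
        is_control=matrix.is_control,
        filter_mask=mask,
        normalization_audit=audit,
    )
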