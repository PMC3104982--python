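"""Synthetic data with the hierarchical structure the analysis assumes.

Two levels of realism are generated:

* :func:`simulate_expression` draws normalized log2 ratios directly from
  the mixed model — per-gene baseline against the common reference, fixed
  sex and LPS effects, and Gaussian random effects for each replication
  level (subject, day, the two LPS interactions, stimulation tube,
  amplification and residual/hybridisation).
* :func:`simulate_spots` expands an expression matrix into spot-level
  two-channel intensity tables with background, a smooth per-print-tip
  dye bias and saturation, to exercise the preprocessing chain; the
  injected distortion is recorded so normalization can be validated as a
  round-trip.

All randomness flows from a single integer seed; the generators are pure
functions of (design, config), so a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    COMPONENTS,
    ArrayDesign,
    DesignMatrixBundle,
    build_design_matrices,
)
from .preprocess import SPOT_COLUMNS, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SpotSimConfig",
    "TruthRecord",
    "simulate_expression",
    "simulate_spots",
    "make_monocyte_table",
    "study_condition_sds",
]

#: Pooled variability reported for the study conditions, log2 scale.
TECHNICAL_SD = 0.16
BIOLOGICAL_SD = 0.06
RESIDUAL_SD = 0.10


def study_condition_sds(
    technical_sd: float = TECHNICAL_SD,
    biological_sd: float = BIOLOGICAL_SD,
    residual_sd: float = RESIDUAL_SD,
) -> dict[str, float]:
    """Per-component generating SDs matching the study's pooled values.

    The residual keeps its own reported SD; stimulation tube and
    amplification split the remaining technical variance equally so the
    pooled technical SD (sqrt of stim + amp + residual variances) equals
    ``technical_sd``; subject and day split the biological variance
    equally; the two LPS-interaction components are zero.
    """
    if residual_sd > technical_sd:
        raise ValueError("residual_sd cannot exceed the pooled technical_sd")
    stim_amp = float(np.sqrt((technical_sd**2 - residual_sd**2) / 2.0))
    subj_day = float(np.sqrt(biological_sd**2 / 2.0))
    return {
        "subject": subj_day,
        "day": subj_day,
        "subject_lps": 0.0,
        "day_lps": 0.0,
        "stim": stim_amp,
        "amp": stim_amp,
        "residual": residual_sd,
    }


@dataclass
class SimulationConfig:
    """Generating parameters for the mixed-model expression simulator.

    ``true_sd`` maps each variance component to the per-gene standard
    deviation of its random effects on the log2 scale — a scalar applies to
    every gene, a length-``n_genes`` vector gives per-gene values.  The LPS
    fixed effect is spike-and-slab across genes: a fraction
    ``lps_effect_nonzero_fraction`` of genes get an effect drawn from
    Normal(0, ``lps_effect_sd``), the rest zero.  ``sex_effect`` is zero by
    default except for ``n_sex_genes`` designated female-specific genes
    ("XIST-like") with effect ``sex_effect_size``.  Gene baselines (offsets
    against the common reference) are Normal(0, ``baseline_sd``).
    """

    n_genes: int = 1000
    true_sd: Mapping[str, float | np.ndarray] = field(default_factory=dict)
    lps_effect_sd: float = 0.0
    lps_effect_nonzero_fraction: float = 0.0
    sex_effect: float | np.ndarray = 0.0
    n_sex_genes: int = 0
    sex_effect_size: float = 0.0
    baseline_sd: float = 1.0
    a_mean: float = 10.0
    a_sd: float = 1.5
    reference_from_day2: bool = False
    reference_artefact_sd: float = 0.05
    seed: int = 0

    def sd_vector(self, component: str) -> np.ndarray:
        v = self.true_sd.get(component, 0.0)
        arr = np.broadcast_to(np.asarray(v, dtype=float), (self.n_genes,)).copy()
        if (arr < 0).any():
            raise ValueError(f"negative SD for component {component}")
        return arr

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not (0 <= self.lps_effect_nonzero_fraction <= 1):
            raise ValueError("lps_effect_nonzero_fraction must be in [0, 1]")
        if self.lps_effect_sd < 0 or self.baseline_sd < 0:
            raise ValueError("SDs must be >= 0")
        unknown = set(self.true_sd) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown variance components: {sorted(unknown)}")
        for c in self.true_sd:
            self.sd_vector(c)


@dataclass
class TruthRecord:
    """Everything the simulator drew: per-gene parameters and all effects."""

    gene_ids: list[str]
    baseline: np.ndarray
    sex_effect: np.ndarray
    lps_effect: np.ndarray
    true_sd: dict[str, np.ndarray]
    random_effects: dict[str, np.ndarray]  # component -> (n_genes, n_levels)
    seed: int

    def frame(self) -> pd.DataFrame:
        data = {
            "gene_id": self.gene_ids,
            "baseline": self.baseline,
            "sex_effect": self.sex_effect,
            "lps_effect": self.lps_effect,
        }
        for c in COMPONENTS:
            data[f"sd_{c}"] = self.true_sd[c]
        return pd.DataFrame(data)

    def write(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)


def simulate_expression(
    design: Sequence[ArrayDesign],
    config: SimulationConfig,
    *,
    bundle: DesignMatrixBundle | None = None,
) -> tuple[ExpressionMatrix, TruthRecord]:
    """Draw an expression matrix from the hierarchical mixed model.

    For gene g on array a,

        M[g, a] = baseline_g + sex_g * female(a) + lps_g * stimulated(a)
                  + sum over components of u[g, level_c(a)],

    with u drawn i.i.d. Normal(0, sd_c(g)^2) per grouping level (null
    interaction levels on unstimulated arrays contribute zero).
    """
    config.validate()
    if bundle is None:
        bundle = build_design_matrices(design)
    for comp in COMPONENTS:
        if comp not in bundle.groupings:
            raise ValueError(f"design bundle missing grouping for {comp}")
    rng = np.random.default_rng(config.seed)
    ng = config.n_genes
    n = bundle.n_arrays
    gene_ids = [f"g{str(i).zfill(max(4, len(str(max(ng - 1, 1)))))}" for i in range(ng)]

    baseline = rng.normal(0.0, config.baseline_sd, size=ng)
    sex_eff = np.broadcast_to(np.asarray(config.sex_effect, dtype=float), (ng,)).copy()
    if config.n_sex_genes:
        sex_eff[: config.n_sex_genes] = config.sex_effect_size
    lps_eff = np.zeros(ng)
    if config.lps_effect_nonzero_fraction > 0 and config.lps_effect_sd > 0 and ng:
        nonzero = rng.random(ng) < config.lps_effect_nonzero_fraction
        lps_eff[nonzero] = rng.normal(0.0, config.lps_effect_sd, size=int(nonzero.sum()))

    female = np.array([1.0 if a.sex == "F" else 0.0 for a in design])
    stim = np.array([float(a.lps) for a in design])

    M = np.empty((ng, n))
    M[:] = baseline[:, None]
    M += sex_eff[:, None] * female[None, :]
    M += lps_eff[:, None] * stim[None, :]

    true_sd: dict[str, np.ndarray] = {}
    random_effects: dict[str, np.ndarray] = {}
    for comp in COMPONENTS:
        sd = config.sd_vector(comp)
        true_sd[comp] = sd
        codes = bundle.groupings[comp]
        nl = bundle.n_levels[comp]
        u = rng.normal(size=(ng, nl)) * sd[:, None]
        random_effects[comp] = u
        active = codes >= 0
        if nl and active.any():
            M[:, active] += u[:, codes[active]]

    if config.reference_from_day2:
        # Common-reference artefact: the pooled reference is built from
        # day-2 unstimulated RNA, so day-2 samples sit closer to it.  A
        # shared per-gene shift is added to all non-day-2 arrays.
        shift = rng.normal(0.0, config.reference_artefact_sd, size=ng)
        day1 = np.array([a.day != 2 for a in design])
        M[:, day1] += shift[:, None]

    a_gene = rng.normal(config.a_mean, config.a_sd, size=ng)
    a_within = a_gene[:, None] + rng.normal(0.0, 0.1, size=(ng, n))

    idx = pd.Index(gene_ids, name="probe_id")
    em = ExpressionMatrix(
        M=pd.DataFrame(M, index=idx, columns=bundle.array_ids),
        A=pd.Series(a_gene, index=idx, name="A"),
        A_within=pd.DataFrame(a_within, index=idx, columns=bundle.array_ids),
    )
    truth = TruthRecord(
        gene_ids=gene_ids,
        baseline=baseline,
        sex_effect=sex_eff,
        lps_effect=lps_eff,
        true_sd=true_sd,
        random_effects=random_effects,
        seed=config.seed,
    )
    return em, truth


# ---------------------------------------------------------------------------
# Spot-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SpotSimConfig:
    """Layout and artefact parameters for spot-level tables.

    The dye bias is a smooth intensity-dependent distortion of M that
    differs per print-tip block (amplitude ``dye_bias_amplitude`` scaled by
    a per-block factor), emulating pin- and intensity-dependent labelling
    differences that print-tip loess is designed to remove.
    """

    n_blocks: int = 4
    n_rows: int = 20
    n_cols: int = 20
    probes_per_gene: int = 1
    control_probe_fraction: float = 0.05
    background_level: float = 80.0
    background_sd: float = 10.0
    dye_bias_amplitude: float = 0.0
    noise_sd: float = 0.0
    offset: float = 50.0
    saturation_ceiling: float = 65535.0
    round_decimals: int | None = 1
    seed: int = 0

    @property
    def capacity(self) -> int:
        return self.n_blocks * self.n_rows * self.n_cols


def _default_dye_bias(a: np.ndarray, block: np.ndarray, amplitude: float, scales: np.ndarray) -> np.ndarray:
    # smooth, nonlinear in A, different magnitude per print-tip block
    return amplitude * scales[block - 1] * np.sin((a - 10.0) / 2.5)


def simulate_spots(
    expression: ExpressionMatrix,
    config: SpotSimConfig,
    *,
    dye_bias: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> dict[str, pd.DataFrame]:
    """Expand an expression matrix into per-array two-channel spot tables.

    By construction, for each spot,

        log2(FG_sample - BG_sample + offset)
          - log2(FG_ref - BG_ref + offset)  ~=  M + dye_bias(A, block),

    so running the preprocessing chain with the same offset and inverting
    the known distortion recovers M — the normalization test oracle.
    Foregrounds are clipped to [0, saturation_ceiling].
    """
    if not np.all(np.isfinite(expression.M.to_numpy())):
        raise ValueError("expression matrix contains non-finite values")
    ng = len(expression.M.index)
    n_library = ng * config.probes_per_gene
    n_controls = int(np.round(n_library * config.control_probe_fraction))
    n_spots = n_library + n_controls
    if n_spots > config.capacity:
        raise ValueError(
            f"grid capacity {config.capacity} < {n_spots} spots (grid overflow)"
        )
    rng = np.random.default_rng(config.seed)

    probe_ids = np.concatenate(
        [
            np.repeat(expression.M.index.to_numpy(), config.probes_per_gene),
            np.array([f"CTRL_{i:04d}" for i in range(n_controls)]),
        ]
    )
    is_control = np.concatenate(
        [np.zeros(n_library, bool), np.ones(n_controls, bool)]
    )
    # spread spots over the grid in a seeded random order so blocks mix
    # control and library probes
    perm = rng.permutation(config.capacity)[:n_spots]
    block = perm // (config.n_rows * config.n_cols) + 1
    rem = perm % (config.n_rows * config.n_cols)
    row = rem // config.n_cols + 1
    col = rem % config.n_cols + 1

    block_scales = rng.uniform(0.5, 1.5, size=config.n_blocks)
    if dye_bias is None:
        def dye_bias(a, b, _amp=config.dye_bias_amplitude, _s=block_scales):
            return _default_dye_bias(a, b, _amp, _s)

    a_base = expression.A.to_numpy()
    a_ctrl = rng.normal(12.0, 0.5, size=n_controls)
    tables: dict[str, pd.DataFrame] = {}
    for j, aid in enumerate(expression.array_ids):
        m_true = np.concatenate(
            [
                np.repeat(expression.M.iloc[:, j].to_numpy(), config.probes_per_gene),
                np.zeros(n_controls),
            ]
        )
        if expression.A_within is not None:
            a_lib = np.repeat(
                expression.A_within.iloc[:, j].to_numpy(), config.probes_per_gene
            )
        else:
            a_lib = np.repeat(a_base, config.probes_per_gene)
        a_spot = np.concatenate([a_lib, a_ctrl])
        m_obs = m_true + dye_bias(a_spot, block)
        if config.noise_sd > 0:
            m_obs = m_obs + rng.normal(0.0, config.noise_sd, size=n_spots)
        target_sample = np.power(2.0, a_spot + m_obs / 2.0)
        target_ref = np.power(2.0, a_spot - m_obs / 2.0)
        bg_s = rng.normal(config.background_level, config.background_sd, size=n_spots)
        bg_r = rng.normal(config.background_level, config.background_sd, size=n_spots)
        bg_s = np.clip(bg_s, 0.0, None)
        bg_r = np.clip(bg_r, 0.0, None)
        fg_s = np.clip(target_sample - config.offset + bg_s, 0.0, config.saturation_ceiling)
        fg_r = np.clip(target_ref - config.offset + bg_r, 0.0, config.saturation_ceiling)
        if config.round_decimals is not None:
            fg_s = np.round(fg_s, config.round_decimals)
            fg_r = np.round(fg_r, config.round_decimals)
            bg_s = np.round(bg_s, config.round_decimals)
            bg_r = np.round(bg_r, config.round_decimals)
        tables[aid] = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "is_control": is_control,
                "block": block,
                "row": row,
                "column": col,
                "FG_sample": fg_s,
                "BG_sample": bg_s,
                "FG_ref": fg_r,
                "BG_ref": bg_r,
            },
            columns=SPOT_COLUMNS,
        )
    return tables


# ---------------------------------------------------------------------------
# Monocyte (CD14+) proportion table
# ---------------------------------------------------------------------------

_MONOCYTE_ROWS = [
    # subject, 0h day1, 0h day2, 24h day1, 24h day2
    ("A", 7.7, 7.1, 6.4, 6.2),
    ("B", 2.3, 7.1, 3.5, 3.2),
    ("C", 5.9, 8.4, 8.2, 11.0),
    ("D", 11.9, 14.6, 7.0, 14.5),
    ("E", 1.8, 2.8, 1.1, 1.6),
]


def make_monocyte_table() -> pd.DataFrame:
    """CD14+ monocyte percentages per subject, day and timepoint.

    Flow-cytometry measurements of the monocyte fraction of PBMC for each
    of the five subjects on both sampling days, before (0 h) and after
    (24 h) LPS stimulation.  Tidy layout: one row per
    (subject, day, timepoint) with a ``percent`` column; 20 cells.
    """
    rows = []
    for subj, d1_0, d2_0, d1_24, d2_24 in _MONOCYTE_ROWS:
        rows.append({"subject": subj, "day": 1, "timepoint": "0h", "percent": d1_0})
        rows.append({"subject": subj, "day": 2, "timepoint": "0h", "percent": d2_0})
        rows.append({"subject": subj, "day": 1, "timepoint": "24h", "percent": d1_24})
        rows.append({"subject": subj, "day": 2, "timepoint": "24h", "percent": d2_24})
    return pd.DataFrame(rows)
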