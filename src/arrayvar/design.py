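"""Hierarchical experimental design for a replicated two-colour array study.

The design emulated here is an in vitro stimulation experiment with
replication at five levels: subjects, sampling days, parallel stimulation
tubes, RNA amplification runs and hybridisations.  Every sample is
hybridised against a common reference, so each array carries one sample
channel and one reference channel.

Two things live here: the per-array annotation (:class:`ArrayDesign`) and
the fixed/random design matrices (:class:`DesignMatrixBundle`) that the
mixed-model fitter consumes.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPONENTS",
    "ArrayDesign",
    "DesignMatrixBundle",
    "build_paper_design",
    "build_design_matrices",
    "validate_design",
    "design_to_frame",
    "design_from_frame",
    "write_design",
    "read_design",
]

#: Random variance components, ordered from outermost (subject) to the
#: innermost residual (hybridisation plus everything downstream of
#: amplification).
COMPONENTS: tuple[str, ...] = (
    "subject",
    "day",
    "subject_lps",
    "day_lps",
    "stim",
    "amp",
    "residual",
)

#: Components whose random levels only act on stimulated arrays.
INTERACTION_COMPONENTS: tuple[str, ...] = ("subject_lps", "day_lps")

DESIGN_COLUMNS = [
    "array_id",
    "subject",
    "day",
    "lps",
    "stim_tube",
    "amp_run",
    "hyb_rep",
    "sex",
    "sample_channel",
]


@dataclass(frozen=True)
class ArrayDesign:
    """Annotation of a single microarray in the replication hierarchy.

    ``stim_tube`` is ``None`` exactly when ``lps`` is 0: unstimulated
    baseline samples are not split into parallel stimulation tubes.
    """

    array_id: str
    subject: str
    day: int
    lps: int
    stim_tube: int | None
    amp_run: int
    hyb_rep: int
    sex: str
    sample_channel: str = "Cy5"

    def key(self) -> tuple:
        return (self.subject, self.day, self.lps, self.stim_tube, self.amp_run, self.hyb_rep)


class DesignError(ValueError):
    """Raised when a design violates the hierarchy invariants."""


def validate_design(design: Sequence[ArrayDesign]) -> None:
    """Check the structural invariants of a design; raise :class:`DesignError`.

    Invariants: stim_tube is null iff lps=0; the six-way replication key is
    unique per array; every stimulated (subject, day) pair has a matched
    unstimulated baseline; sex is constant within subject.
    """
    if not design:
        raise DesignError("empty design")
    keys = set()
    sex_by_subject: dict[str, str] = {}
    stim_pairs = set()
    unstim_pairs = set()
    for a in design:
        if (a.stim_tube is None) != (a.lps == 0):
            raise DesignError(
                f"array {a.array_id}: stim_tube must be null exactly when lps=0"
            )
        if a.key() in keys:
            raise DesignError(f"duplicate replication key for array {a.array_id}")
        keys.add(a.key())
        prev = sex_by_subject.setdefault(a.subject, a.sex)
        if prev != a.sex:
            raise DesignError(f"subject {a.subject} has inconsistent sex")
        if a.lps:
            stim_pairs.add((a.subject, a.day))
        else:
            unstim_pairs.add((a.subject, a.day))
    missing = stim_pairs - unstim_pairs
    if missing:
        raise DesignError(f"stimulated samples without unstimulated baseline: {sorted(missing)}")


def _default_sexes(n_subjects: int) -> list[str]:
    # 2F/3M for five subjects (the study panel); interleaved so smaller
    # designs keep both sexes and the sex contrast stays estimable.
    pattern = ["F", "M", "F", "M", "M"]
    return [pattern[i % 5] for i in range(n_subjects)]


def build_paper_design(
    n_subjects: int = 5,
    full_replication_subjects: int = 2,
    *,
    extra_amp_arrays: int = 1,
    extra_hyb_arrays: int = 2,
    sexes: Sequence[str] | None = None,
) -> list[ArrayDesign]:
    """Build the replicated study design.

    Every subject is sampled on 2 days; on each day one unstimulated
    baseline and two parallel LPS-stimulation tubes are each amplified and
    hybridised once (the 30-array skeleton for 5 subjects).  The first
    ``full_replication_subjects`` subjects additionally carry, on day 1 /
    stimulation tube 1, ``extra_amp_arrays`` arrays from repeat
    amplification runs and ``extra_hyb_arrays`` repeat hybridisations of
    the first amplification.  The defaults give 36 arrays for 5 subjects
    with 2 fully replicated subjects.
    """
    if n_subjects < 1:
        raise DesignError("n_subjects must be >= 1")
    if full_replication_subjects > n_subjects:
        raise DesignError("full_replication_subjects cannot exceed n_subjects")
    if sexes is None:
        sexes = _default_sexes(n_subjects)
    if len(sexes) != n_subjects:
        raise DesignError("sexes must have one entry per subject")

    subjects = [chr(ord("A") + i) for i in range(n_subjects)]
    arrays: list[ArrayDesign] = []

    def add(subj_i: int, day: int, lps: int, tube: int | None, amp: int, hyb: int) -> None:
        tube_lbl = "0" if tube is None else str(tube)
        aid = f"{subjects[subj_i]}d{day}L{lps}t{tube_lbl}a{amp}h{hyb}"
        arrays.append(
            ArrayDesign(
                array_id=aid,
                subject=subjects[subj_i],
                day=day,
                lps=lps,
                stim_tube=tube,
                amp_run=amp,
                hyb_rep=hyb,
                sex=sexes[subj_i],
            )
        )

    for i in range(n_subjects):
        for day in (1, 2):
            add(i, day, 0, None, 1, 1)
            add(i, day, 1, 1, 1, 1)
            add(i, day, 1, 2, 1, 1)
    for i in range(full_replication_subjects):
        for k in range(extra_hyb_arrays):
            add(i, 1, 1, 1, 1, 2 + k)
        for k in range(extra_amp_arrays):
            add(i, 1, 1, 1, 2 + k, 1)

    validate_design(arrays)
    return arrays


# ---------------------------------------------------------------------------
# Tabular round-trip (tab-delimited design file, "NA" for null stim_tube)
# ---------------------------------------------------------------------------

def design_to_frame(design: Sequence[ArrayDesign]) -> pd.DataFrame:
    rows = []
    for a in design:
        rows.append(
            {
                "array_id": a.array_id,
                "subject": a.subject,
                "day": a.day,
                "lps": a.lps,
                "stim_tube": "NA" if a.stim_tube is None else a.stim_tube,
                "amp_run": a.amp_run,
                "hyb_rep": a.hyb_rep,
                "sex": a.sex,
                "sample_channel": a.sample_channel,
            }
        )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def design_from_frame(frame: pd.DataFrame) -> list[ArrayDesign]:
    missing = set(DESIGN_COLUMNS) - set(frame.columns)
    if missing:
        raise DesignError(f"design file missing columns: {sorted(missing)}")
    design = []
    for _, r in frame.iterrows():
        tube = r["stim_tube"]
        tube = None if (pd.isna(tube) or str(tube) == "NA") else int(tube)
        design.append(
            ArrayDesign(
                array_id=str(r["array_id"]),
                subject=str(r["subject"]),
                day=int(r["day"]),
                lps=int(r["lps"]),
                stim_tube=tube,
                amp_run=int(r["amp_run"]),
                hyb_rep=int(r["hyb_rep"]),
                sex=str(r["sex"]),
                sample_channel=str(r["sample_channel"]),
            )
        )
    validate_design(design)
    return design


def write_design(design: Sequence[ArrayDesign], path) -> None:
    design_to_frame(design).to_csv(path, sep="\t", index=False)


def read_design(path) -> list[ArrayDesign]:
    return design_from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrixBundle:
    """Fixed-effect incidence matrix plus random-effect groupings.

    ``groupings`` maps each variance component to an integer level code per
    array; ``-1`` marks the null level of an interaction component on
    unstimulated arrays (those rows contribute no random effect).  The
    residual grouping gives every array its own level.
    """

    array_ids: list[str]
    X: np.ndarray
    fixed_names: list[str]
    groupings: dict[str, np.ndarray]
    n_levels: dict[str, int]
    unidentifiable: set[str] = field(default_factory=set)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    def incidence(self, component: str) -> np.ndarray:
        """Dense indicator matrix Z (arrays x levels) for one component."""
        codes = self.groupings[component]
        Z = np.zeros((len(codes), self.n_levels[component]))
        seen = codes >= 0
        Z[np.nonzero(seen)[0], codes[seen]] = 1.0
        return Z


def _codes(keys: list[tuple]) -> tuple[np.ndarray, int]:
    levels: dict[tuple, int] = {}
    out = np.empty(len(keys), dtype=np.int64)
    for i, k in enumerate(keys):
        if k is None:
            out[i] = -1
            continue
        out[i] = levels.setdefault(k, len(levels))
    return out, len(levels)


def build_design_matrices(
    design: Sequence[ArrayDesign],
    *,
    day_nested_in_subject: bool = True,
) -> DesignMatrixBundle:
    """Construct fixed and random design structures for the mixed model.

    Fixed effects: intercept (unstimulated male baseline against the
    reference), sex contrast (F - M) and LPS treatment (stimulated -
    unstimulated).  Aliased fixed columns (e.g. single-sex designs) are
    dropped with a warning, not an error.

    Random groupings follow the replication hierarchy: day is nested in
    subject by default (crossed coding via ``day_nested_in_subject=False``),
    stimulation tube, amplification run and hybridisation are nested in
    their parent sample.  The two interaction components act only on
    stimulated arrays; unstimulated arrays sit in a null level.
    Components whose variance cannot be separated from the fixed effects or
    from a finer component are flagged in ``unidentifiable``.
    """
    validate_design(design)
    n = len(design)
    array_ids = [a.array_id for a in design]

    sex = np.array([1.0 if a.sex == "F" else 0.0 for a in design])
    lps = np.array([float(a.lps) for a in design])
    X = np.column_stack([np.ones(n), sex, lps])
    names = ["intercept", "sex", "lps"]
    # Drop aliased columns (constant or linearly dependent), keep intercept.
    keep = [0]
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(
                f"fixed effect '{names[j]}' is aliased and was dropped",
                UserWarning,
                stacklevel=2,
            )
    fixed_names = [names[j] for j in keep]
    X = X[:, keep]

    day_key = (
        (lambda a: (a.subject, a.day))
        if day_nested_in_subject
        else (lambda a: (a.day,))
    )
    keymakers = {
        "subject": lambda a: (a.subject,),
        "day": day_key,
        "subject_lps": lambda a: (a.subject,) if a.lps else None,
        "day_lps": (lambda a: day_key(a) if a.lps else None),
        "stim": lambda a: (a.subject, a.day, a.lps, a.stim_tube),
        "amp": lambda a: (a.subject, a.day, a.lps, a.stim_tube, a.amp_run),
        "residual": lambda a: (a.array_id,),
    }
    groupings: dict[str, np.ndarray] = {}
    n_levels: dict[str, int] = {}
    for comp, km in keymakers.items():
        codes, nl = _codes([km(a) for a in design])
        groupings[comp] = codes
        n_levels[comp] = nl

    bundle = DesignMatrixBundle(
        array_ids=array_ids,
        X=X,
        fixed_names=fixed_names,
        groupings=groupings,
        n_levels=n_levels,
    )
    bundle.unidentifiable = _find_unidentifiable(bundle)
    return bundle


def _find_unidentifiable(bundle: DesignMatrixBundle) -> set[str]:
    """Flag variance components whose parameter the design cannot estimate.

    A component is unidentifiable when its incidence, after projecting out
    the fixed effects, vanishes (e.g. a single-subject design aliases the
    subject effect with the intercept), or when its grouping partition
    coincides with a strictly finer component's partition (the pair is then
    completely confounded and only the finer one is kept).
    """
    X = bundle.X
    Q, _ = np.linalg.qr(X)
    flagged: set[str] = set()
    zmats = {c: bundle.incidence(c) for c in COMPONENTS}
    for comp in COMPONENTS:
        if comp == "residual":
            continue
        Z = zmats[comp]
        resid = Z - Q @ (Q.T @ Z)
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(Z)):
            flagged.add(comp)
    order = list(COMPONENTS)
    for i, comp in enumerate(order[:-1]):
        if comp in flagged:
            continue
        Gi = zmats[comp] @ zmats[comp].T
        for finer in order[i + 1 :]:
            Gj = zmats[finer] @ zmats[finer].T
            if np.allclose(Gi, Gj):
                flagged.add(comp)
                break
    return flagged
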