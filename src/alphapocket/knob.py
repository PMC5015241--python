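"""Knob-level statistics of a binding-site curvature profile.

The *average convex degree* (ACD) of one SA vector is the mean SA over its
convex atoms — those with SA strictly above a small threshold ``t`` (the
threshold removes near-zero values that would otherwise dominate the mean).
Two per-mutant summaries, the *knob level*, are defined on an F × A profile:

* **Method A** (per-frame): the mean of the F per-frame ACDs.
* **Method B** (average site): the ACD of the A per-atom trajectory means —
  the "average binding site".

For a single frame, or a profile constant across frames, the two methods
coincide.  Higher knob levels mean a more protrusion-studded (knobbier)
pocket; in the drug-response setting, pockets of responding variants sit at
lower knob levels than non-responding ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .curvature import CurvatureProfile

logger = logging.getLogger(__name__)

#: Solid-angle thresholds conventionally examined; 0.01 gives the best grouping.
DEFAULT_THRESHOLDS = (0.0, 0.01, 0.02)
DEFAULT_THRESHOLD = 0.01


@dataclass
class KnobResult:
    """Knob level of one mutant (one method, one threshold)."""

    mutant_id: str
    method: Literal["A", "B"]
    threshold: float
    knob_level: float
    per_frame_acd: np.ndarray | None = None   # method A: F values
    mean_site_sa: np.ndarray | None = None    # method B: A values
    n_convex_used: int = 0
    n_empty_frames: int = 0


@dataclass
class CohortRecord:
    """One mutant of a response cohort: clinical level plus knob levels.

    ``rl`` is the 4-level drug response (1 complete response, 2 partial
    response, 3 stable disease, 4 progressive disease); the binary group
    merges 1–2 into "Response" and 3–4 into "No-response".
    """

    mutant_id: str
    rl: int
    knob_a: float = float("nan")
    knob_b: float = float("nan")
    group: str = field(init=False)

    def __post_init__(self) -> None:
        if self.rl not in (1, 2, 3, 4):
            raise ValueError(f"{self.mutant_id}: RL must be 1..4, got {self.rl}")
        self.group = "Response" if self.rl <= 2 else "No-response"

    def knob(self, which: Literal["A", "B"]) -> float:
        return self.knob_a if which == "A" else self.knob_b


def median_response_level(patient_rls: Sequence[int]) -> int:
    """Mutant-level RL from patient-level RLs: the lower median.

    With an even patient count the smaller of the two middle values is taken
    (ties round down), so the result is always one of the observed levels.
    """
    vals = sorted(int(r) for r in patient_rls)
    if not vals:
        raise ValueError("no patient response levels given")
    return vals[(len(vals) - 1) // 2]


def average_convex_degree(sa_row: np.ndarray, t: float = 0.0) -> float:
    """Mean SA over convex atoms (SA > t) of one SA vector; 0 if none.

    The empty-convex-set convention (return 0, log a warning) keeps frames
    without any convex atom well-defined; they are counted by the callers.
    """
    if t < 0:
        raise ValueError("threshold must be ≥ 0")
    sa_row = np.asarray(sa_row, dtype=float)
    convex = sa_row[sa_row > t]
    if convex.size == 0:
        logger.warning("average_convex_degree: no convex atom above t=%g", t)
        return 0.0
    return float(convex.mean())


def knob_level_method_a(profile: CurvatureProfile, t: float = DEFAULT_THRESHOLD,
                        mutant_id: str = "") -> KnobResult:
    """Method A: mean over frames of the per-frame average convex degree."""
    sa = profile.sa_matrix
    acd = np.empty(sa.shape[0])
    n_convex = 0
    n_empty = 0
    for f in range(sa.shape[0]):
        convex = sa[f][sa[f] > t]
        if convex.size == 0:
            acd[f] = 0.0
            n_empty += 1
        else:
            acd[f] = convex.mean()
            n_convex += convex.size
    if n_empty:
        logger.warning("%s: %d/%d frames had no convex atom above t=%g",
                       mutant_id or "profile", n_empty, sa.shape[0], t)
    return KnobResult(mutant_id=mutant_id, method="A", threshold=t,
                      knob_level=float(acd.mean()), per_frame_acd=acd,
                      n_convex_used=n_convex, n_empty_frames=n_empty)


def knob_level_method_b(profile: CurvatureProfile, t: float = DEFAULT_THRESHOLD,
                        mutant_id: str = "") -> KnobResult:
    """Method B: average convex degree of the per-atom trajectory-mean SA."""
    mean_site = profile.sa_matrix.mean(axis=0)
    convex = mean_site[mean_site > t]
    kl = average_convex_degree(mean_site, t)
    return KnobResult(mutant_id=mutant_id, method="B", threshold=t,
                      knob_level=kl, mean_site_sa=mean_site,
                      n_convex_used=int(convex.size),
                      n_empty_frames=0)


def knob_level(profile: CurvatureProfile, t: float = DEFAULT_THRESHOLD,
               method: Literal["A", "B"] = "A", mutant_id: str = "") -> KnobResult:
    fn = knob_level_method_a if method == "A" else knob_level_method_b
    return fn(profile, t, mutant_id)


def atom_count_stats(sa, cutoffs: Sequence[float] = (0.0, 0.5, -0.5, 0.7)):
    """Atom counts above/below SA cutoffs.

    For each cutoff ``c``: the count of atoms with ``SA > c`` when c ≥ 0
    (convex-side statistics: convex atoms at c = 0, strongly convex at 0.5
    or 0.7) and with ``SA < c`` when c < 0 (concave side).  A 1-D input (one
    frame, or an averaged site) gives integer counts; a 2-D F × A input gives
    per-frame count arrays.
    """
    sa = np.asarray(sa, dtype=float)
    if sa.ndim not in (1, 2):
        raise ValueError("sa must be 1-D or 2-D")
    axis = -1
    out: dict[float, int | np.ndarray] = {}
    for c in cutoffs:
        counts = (sa > c).sum(axis=axis) if c >= 0 else (sa < c).sum(axis=axis)
        out[float(c)] = int(counts) if sa.ndim == 1 else counts.astype(int)
    return out


def cohort_to_dataframe(records: Sequence[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mutant_id": r.mutant_id, "rl": r.rl, "group": r.group,
        "knob_a": r.knob_a, "knob_b": r.knob_b,
    } for r in records])


def read_cohort_csv(path) -> list[CohortRecord]:
    """Read a cohort table: columns ``mutant_id, rl`` (wide) or
    ``mutant_id, patient_id, rl`` (patient-level long format, aggregated by
    the lower median per mutant)."""
    df = pd.read_csv(path)
    if "mutant_id" not in df.columns or "rl" not in df.columns:
        raise ValueError("cohort CSV needs columns mutant_id, rl")
    if "patient_id" in df.columns:
        agg = df.groupby("mutant_id", sort=False)["rl"].apply(
            lambda s: median_response_level(s.tolist()))
        return [CohortRecord(mutant_id=str(m), rl=int(r)) for m, r in agg.items()]
    return [CohortRecord(mutant_id=str(m), rl=int(r))
            for m, r in zip(df["mutant_id"], df["rl"])]
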