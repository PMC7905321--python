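"""Fetal gene editing with SCNT cloning and embryo transfer.

The modelled editing step converts the top-merit non-PP seedstock bull
calves of a year to homozygous polled before birth: fetal tissue is
genotyped and sorted on TBV, the chosen fetuses are edited and the edited
cell line is cloned into a calf by somatic cell nuclear transfer (SCNT)
and embryo transfer (ET).  Each editing/ET cycle succeeds with probability
``edit_success * et_success`` and cycles are repeated until one succeeds,
so every selected calf is ultimately born homozygous polled, in the same
year, with its TBV, sex, pedigree links and herd unchanged (the clone
carries the selected genome); only the genotype and the edited flag change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import Fate, Herdbook, Sector, Sex


@dataclass(frozen=True)
class EditAttemptRecord:
    calf_id: int
    editing_attempts: int  # total editing/ET cycles until joint success
    et_attempts: int  # cycles in which the edit succeeded and ET was tried
    success_year: int


def select_edit_candidates(
    hb: Herdbook, calf_ids: np.ndarray, edit_fraction: float
) -> np.ndarray:
    """Choose the year's editing candidates among seedstock bull calves.

    The quota is ``edit_fraction`` times the number of seedstock bull calves
    born that year, rounded to the nearest integer (at least 1 whenever the
    fraction is positive and an eligible calf exists).  Eligibility is
    restricted to non-PP calves — heterozygous polled and horned fetuses —
    sorted by descending TBV, ties by id; when fewer eligible calves exist
    than the quota, all are selected.
    """
    if not 0.0 <= edit_fraction <= 1.0:
        raise ValueError("edit_fraction must be in [0, 1]")
    calf_ids = np.asarray(calf_ids, dtype=np.int64)
    bull_calves = calf_ids[
        (hb.sex[calf_ids] == Sex.MALE) & (hb.sector[calf_ids] == Sector.SEEDSTOCK)
    ]
    if edit_fraction == 0.0 or bull_calves.size == 0:
        return np.empty(0, dtype=np.int64)
    pool = bull_calves[hb.genotype[bull_calves] != 2]
    if pool.size == 0:
        return np.empty(0, dtype=np.int64)
    quota = max(1, round(edit_fraction * bull_calves.size))
    order = np.lexsort((pool, -hb.tbv[pool]))
    return pool[order][:quota]


def perform_edits(
    hb: Herdbook,
    candidate_ids: np.ndarray,
    edit_success: float,
    et_success: float,
    year: int,
    rng: np.random.Generator,
) -> list[EditAttemptRecord]:
    """Edit the selected calves to homozygous polled; log the attempt counts.

    Each cycle attempts an edit (success ``edit_success``) and, if the edit
    took, an ET (success ``et_success``); the cycle count to first joint
    success is geometric with p = edit_success * et_success.  ET attempts
    are the cycles whose edit succeeded: one (the final success) plus a
    binomial share of the failed cycles.
    """
    candidate_ids = np.asarray(candidate_ids, dtype=np.int64)
    if candidate_ids.size == 0:
        return []
    p_joint = edit_success * et_success
    if not 0.0 < p_joint <= 1.0:
        raise ValueError("joint editing/ET success probability must be in (0, 1]")
    cycles = rng.geometric(p_joint, candidate_ids.size)
    # P(edit succeeded | cycle failed overall) = p_e (1 - p_et) / (1 - p_e p_et)
    if p_joint < 1.0:
        p_cond = edit_success * (1.0 - et_success) / (1.0 - p_joint)
        et_tries = 1 + rng.binomial(cycles - 1, p_cond)
    else:
        et_tries = np.ones_like(cycles)

    hb.genotype[candidate_ids] = 2
    hb.edited[candidate_ids] = True

    return [
        EditAttemptRecord(int(c), int(n), int(e), year)
        for c, n, e in zip(candidate_ids, cycles, et_tries)
    ]
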