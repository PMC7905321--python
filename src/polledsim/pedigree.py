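"""Pedigree bookkeeping and exact inbreeding coefficients.

The registry is an append-only parent map.  Animal ids are assigned in birth
order, so the pedigree is topologically sorted by construction and every
parent id is strictly smaller than its offspring's id.  Unknown parents are
treated as unique, unrelated, non-inbred founders.

Inbreeding coefficients are Wright's f computed exactly from the recorded
pedigree with the recursive-kinship (tabular) method of Meuwissen & Luo,
implemented as a numba kernel so that whole birth cohorts can be evaluated
incrementally as the simulation runs.  f of an animal equals half the
additive relationship between its parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

#: Sentinel for an unknown parent.
UNKNOWN = -1


@dataclass(frozen=True)
class PedigreeRecord:
    animal_id: int
    sire_id: int  # UNKNOWN (-1) if not recorded
    dam_id: int
    f: float


@njit(cache=False)
def _ml_extend(sire, dam, F, start, n):  # pragma: no cover - exercised via wrapper
    # Meuwissen & Luo (1992) inbreeding algorithm, incremental form.
    # sire/dam are int64 arrays with -1 for unknown; F[:start] is already
    # computed.  For each new animal the list of its distinct ancestors is
    # traced with a descending-id linked list (point) while accumulating the
    # ancestor contributions L; then
    #   f_i = sum_j L_j^2 * (0.5 - 0.25 (F_sj + F_dj)) - 1
    # with F of an unknown parent taken as -1.
    L = np.zeros(n, np.float64)
    point = np.full(n, -2, np.int64)  # -2 = not in list, -1 = list terminator
    for i in range(start, n):
        si = sire[i]
        di = dam[i]
        if si < 0 or di < 0:
            F[i] = 0.0
            continue
        if i > start and si == sire[i - 1] and di == dam[i - 1]:
            F[i] = F[i - 1]  # full sib of the previous animal
            continue
        fi = -1.0
        L[i] = 1.0
        point[i] = -1
        j = i
        while j >= 0:
            k = j
            r = 0.5 * L[k]
            a = sire[k]
            b = dam[k]
            if a < b:
                a, b = b, a
            if a >= 0:
                while point[k] > a:
                    k = point[k]
                L[a] += r
                if a != point[k]:
                    point[a] = point[k]
                    point[k] = a
                if b >= 0:
                    while point[k] > b:
                        k = point[k]
                    L[b] += r
                    if b != point[k]:
                        point[b] = point[k]
                        point[k] = b
            sj = sire[j]
            dj = dam[j]
            fs = F[sj] if sj >= 0 else -1.0
            fd = F[dj] if dj >= 0 else -1.0
            fi += L[j] * L[j] * (0.5 - 0.25 * (fs + fd))
            L[j] = 0.0
            nxt = point[j]
            point[j] = -2
            j = nxt
        F[i] = fi


class PedigreeRegistry:
    """Append-only pedigree with lazily extended inbreeding coefficients."""

    def __init__(self, capacity: int = 1024):
        self._sire = np.full(max(capacity, 16), UNKNOWN, dtype=np.int64)
        self._dam = np.full(max(capacity, 16), UNKNOWN, dtype=np.int64)
        self._f = np.zeros(max(capacity, 16), dtype=np.float64)
        self._n = 0
        self._computed = 0  # f is valid for ids < _computed

    # -- structure ---------------------------------------------------------

    def __len__(self) -> int:
        return self._n

    @property
    def sire_ids(self) -> np.ndarray:
        return self._sire[: self._n]

    @property
    def dam_ids(self) -> np.ndarray:
        return self._dam[: self._n]

    def _grow(self, need: int) -> None:
        cap = self._sire.shape[0]
        if self._n + need <= cap:
            return
        new_cap = max(cap * 2, self._n + need)
        for name in ("_sire", "_dam", "_f"):
            old = getattr(self, name)
            arr = np.full(new_cap, UNKNOWN, old.dtype) if old.dtype.kind == "i" else np.zeros(new_cap, old.dtype)
            arr[: self._n] = old[: self._n]
            setattr(self, name, arr)

    def register_batch(self, sire_ids, dam_ids) -> np.ndarray:
        """Register a birth cohort; returns the newly assigned ids."""
        s = np.asarray(sire_ids, dtype=np.int64)
        d = np.asarray(dam_ids, dtype=np.int64)
        if s.shape != d.shape:
            raise ValueError("sire and dam id arrays must have the same length")
        k = s.shape[0]
        ids = np.arange(self._n, self._n + k, dtype=np.int64)
        # parents may come from this same birth-ordered batch, but must be
        # strictly older (smaller id) than their offspring
        if k and (np.any(s >= ids) or np.any(d >= ids)):
            raise ValueError("parent ids must be registered before their offspring")
        if k and (s.min(initial=0) < UNKNOWN or d.min(initial=0) < UNKNOWN):
            raise ValueError("parent ids must be >= -1 (unknown)")
        self._grow(k)
        self._sire[ids] = s
        self._dam[ids] = d
        self._n += k
        return ids

    def register(self, animal_id: int | None = None, sire_id=None, dam_id=None) -> PedigreeRecord:
        """Register one animal.

        ``animal_id``, if given, must equal the next id in birth order (ids
        are dense and strictly increasing); this rejects duplicate ids and,
        together with the parent checks, any parent younger than its child.
        ``None`` parents mean unknown.
        """
        if animal_id is not None and int(animal_id) != self._n:
            if int(animal_id) < self._n:
                raise ValueError(f"animal id {animal_id} is already registered")
            raise ValueError(f"ids are assigned in birth order; expected {self._n}, got {animal_id}")
        s = UNKNOWN if sire_id is None else int(sire_id)
        d = UNKNOWN if dam_id is None else int(dam_id)
        new = self.register_batch([s], [d])[0]
        return self.record(int(new))

    # -- inbreeding --------------------------------------------------------

    def _ensure_computed(self) -> None:
        if self._computed < self._n:
            _ml_extend(self._sire, self._dam, self._f, self._computed, self._n)
            self._computed = self._n

    def inbreeding(self, animal_id: int) -> float:
        """Wright's inbreeding coefficient of one registered animal."""
        i = int(animal_id)
        if not 0 <= i < self._n:
            raise KeyError(f"animal id {animal_id} is not registered")
        self._ensure_computed()
        return float(self._f[i])

    def inbreeding_of(self, ids) -> np.ndarray:
        """Inbreeding coefficients for an array of registered ids."""
        ids = np.asarray(ids, dtype=np.int64)
        if ids.size and (ids.min() < 0 or ids.max() >= self._n):
            raise KeyError("unregistered animal id")
        self._ensure_computed()
        return self._f[ids]

    @property
    def inbreeding_all(self) -> np.ndarray:
        self._ensure_computed()
        return self._f[: self._n]

    def record(self, animal_id: int) -> PedigreeRecord:
        f = self.inbreeding(animal_id)
        return PedigreeRecord(
            animal_id=int(animal_id),
            sire_id=int(self._sire[animal_id]),
            dam_id=int(self._dam[animal_id]),
            f=f,
        )

    # -- export ------------------------------------------------------------

    def write(self, path) -> None:
        """Write the standard three-column pedigree text file.

        One ``animal sire dam`` record per line, birth-ordered, ids 1-based
        with 0 for an unknown parent.
        """
        with open(path, "w") as fh:
            for i in range(self._n):
                fh.write(f"{i + 1} {self._sire[i] + 1} {self._dam[i] + 1}\n")


def mendelian_sampling_variance(f_sire, f_dam, sigma_a2):
    """Variance of the Mendelian sampling deviation of a calf's breeding value.

    Returns ``0.5 * (1 - 0.5 * (f_S + f_D)) * sigma_a2``: half the additive
    genetic variance, shrunk by the mean parental inbreeding (inbred parents
    transmit less within-family variation).  Accepts scalars or arrays.
    """
    f_s = np.asarray(f_sire, dtype=np.float64)
    f_d = np.asarray(f_dam, dtype=np.float64)
    if np.any(f_s < 0) or np.any(f_s > 1) or np.any(f_d < 0) or np.any(f_d > 1):
        raise ValueError("inbreeding coefficients must lie in [0, 1]")
    if np.any(np.asarray(sigma_a2) < 0):
        raise ValueError("additive genetic variance must be non-negative")
    out = 0.5 * (1.0 - 0.5 * (f_s + f_d)) * sigma_a2
    return float(out) if np.isscalar(f_sire) and np.isscalar(f_dam) else out


def expected_inbreeding_rate(n_sires: int, n_dams: int) -> float:
    """Per-generation inbreeding rate expected from parent numbers alone.

    The classical idealised-population approximation 1/(8 N_m) + 1/(8 N_f),
    which ignores relatedness among the parents and therefore bounds the
    pedigree-based estimate from below.
    """
    if n_sires < 1 or n_dams < 1:
        raise ValueError("parent counts must be at least 1")
    return 1.0 / (8.0 * n_sires) + 1.0 / (8.0 * n_dams)
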