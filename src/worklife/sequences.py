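"""Optimal-matching dissimilarities between categorical state sequences.

The employment history of each person is a length-28 sequence of yearly
work-schedule states (ages 22-49) over the five-token alphabet
``NW, ST, EV, NI, VH`` (not working, standard, evening, night, variable
hours).  Dissimilarity between two sequences is the classic optimal-matching
(OM) edit distance: the minimum total cost of insertions/deletions (each at
the indel cost) and substitutions (costed by a symmetric state-pair matrix)
that turn one sequence into the other, computed with the Needleman-Wunsch
dynamic program.  Substitution costs are derived from observed year-to-year
transition rates ("TRATE"): rare transitions cost more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

#: canonical work-schedule state alphabet
STATES: tuple[str, ...] = ("NW", "ST", "EV", "NI", "VH")

#: number of yearly observations, ages 22 through 49 inclusive
N_AGES: int = 28
AGE_MIN: int = 22

MISSING: int = -1  # integer code for a missing state


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SequencePanel:
    """Person x age grid of categorical states.

    Parameters
    ----------
    ids
        Person identifiers, length ``n``.
    codes
        ``(n, T)`` integer array; values index into ``alphabet``; ``-1``
        marks a missing observation.
    alphabet
        Ordered state vocabulary.
    """

    ids: np.ndarray
    codes: np.ndarray
    alphabet: tuple[str, ...] = STATES

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D person x age array")
        if len(self.ids) != self.codes.shape[0]:
            raise ValueError("ids and codes disagree on the number of persons")
        bad = (self.codes >= len(self.alphabet)) | (
            (self.codes < 0) & (self.codes != MISSING)
        )
        if bad.any():
            raise ValueError("state codes outside the alphabet")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def n_ages(self) -> int:
        return self.codes.shape[1]

    @property
    def ages(self) -> np.ndarray:
        return np.arange(AGE_MIN, AGE_MIN + self.n_ages)

    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())

    # -- construction -------------------------------------------------------

    @classmethod
    def from_states(
        cls, states, ids=None, alphabet: tuple[str, ...] = STATES
    ) -> "SequencePanel":
        """Build a panel from an ``(n, T)`` array-like of state tokens."""
        states = np.asarray(states, dtype=object)
        lookup = {s: i for i, s in enumerate(alphabet)}
        codes = np.full(states.shape, MISSING, dtype=np.int16)
        for tok, code in lookup.items():
            codes[states == tok] = code
        unknown = (codes == MISSING) & ~pd.isna(states)
        if unknown.any():
            bad = sorted(set(states[unknown].ravel()))
            raise ValueError(f"unknown state tokens: {bad}")
        if ids is None:
            ids = np.arange(states.shape[0])
        return cls(ids=np.asarray(ids), codes=codes, alphabet=alphabet)

    @classmethod
    def from_long(
        cls, frame: pd.DataFrame, alphabet: tuple[str, ...] = STATES
    ) -> "SequencePanel":
        """Read the long format (columns ``person_id, age, state``)."""
        wide = frame.pivot(index="person_id", columns="age", values="state")
        wide = wide.reindex(columns=sorted(wide.columns))
        return cls.from_states(wide.to_numpy(), ids=wide.index.to_numpy(), alphabet=alphabet)

    @classmethod
    def from_wide(
        cls, frame: pd.DataFrame, alphabet: tuple[str, ...] = STATES
    ) -> "SequencePanel":
        """Read the wide format (``person_id`` plus one ``age_*`` column per age)."""
        age_cols = [c for c in frame.columns if c.startswith("age_")]
        age_cols.sort(key=lambda c: int(c.split("_")[1]))
        return cls.from_states(
            frame[age_cols].to_numpy(),
            ids=frame["person_id"].to_numpy(),
            alphabet=alphabet,
        )

    # -- export -------------------------------------------------------------

    def to_tokens(self) -> np.ndarray:
        out = np.empty(self.codes.shape, dtype=object)
        out[:] = None
        for i, tok in enumerate(self.alphabet):
            out[self.codes == i] = tok
        return out

    def to_long(self) -> pd.DataFrame:
        toks = self.to_tokens()
        n, t = toks.shape
        return pd.DataFrame(
            {
                "person_id": np.repeat(self.ids, t),
                "age": np.tile(self.ages, n),
                "state": toks.ravel(),
            }
        )

    def to_wide(self) -> pd.DataFrame:
        toks = self.to_tokens()
        frame = pd.DataFrame(toks, columns=[f"age_{a}" for a in self.ages])
        frame.insert(0, "person_id", self.ids)
        return frame

    # -- preprocessing ------------------------------------------------------

    def fill_gaps(self) -> "SequencePanel":
        """Resolve missing states before distance computation.

        Last observation carried forward; leading gaps are back-filled from
        the first observed state.  Persons with no observed state at all
        remain missing and should be removed by the cohort filter.
        """
        codes = self.codes.copy()
        for row in codes:
            obs = np.flatnonzero(row != MISSING)
            if obs.size == 0:
                continue
            # back-fill the leading gap
            row[: obs[0]] = row[obs[0]]
            last = row[obs[0]]
            for t in range(obs[0], row.size):
                if row[t] == MISSING:
                    row[t] = last
                else:
                    last = row[t]
        return SequencePanel(ids=self.ids.copy(), codes=codes, alphabet=self.alphabet)

    def subset(self, mask) -> "SequencePanel":
        return SequencePanel(
            ids=self.ids[mask], codes=self.codes[mask], alphabet=self.alphabet
        )


@dataclass
class TransitionMatrix:
    """Row-stochastic matrix of year-to-year state transition rates."""

    rates: np.ndarray
    alphabet: tuple[str, ...] = STATES
    unobserved_origins: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        k = len(self.alphabet)
        if self.rates.shape != (k, k):
            raise ValueError("transition matrix shape does not match alphabet")
        if ((self.rates < 0) | (self.rates > 1)).any():
            raise ValueError("transition rates outside [0, 1]")
        rowsum = self.rates.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("transition-rate rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rates, index=self.alphabet, columns=self.alphabet)


@dataclass
class CostModel:
    """Indel cost plus symmetric substitution-cost matrix."""

    indel: float
    sub: np.ndarray
    alphabet: tuple[str, ...] = STATES

    def __post_init__(self) -> None:
        self.sub = np.asarray(self.sub, dtype=float)
        k = len(self.alphabet)
        if self.sub.shape != (k, k):
            raise ValueError("substitution matrix shape does not match alphabet")
        if self.indel < 0:
            raise ValueError("indel cost must be nonnegative")
        if not np.allclose(self.sub, self.sub.T):
            raise ValueError("substitution matrix must be symmetric")
        if not np.allclose(np.diag(self.sub), 0.0):
            raise ValueError("substitution matrix must have zero diagonal")
        if (self.sub < 0).any():
            raise ValueError("substitution costs must be nonnegative")
        if (self.sub > 2 * self.indel + 1e-12).any():
            warnings.warn(
                "some substitution costs exceed 2*indel; a delete+insert pair "
                "then undercuts the substitution and the matrix entry is never used",
                stacklevel=2,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sub, index=self.alphabet, columns=self.alphabet)


@dataclass
class DistanceMatrix:
    """Condensed (upper-triangular) symmetric OM dissimilarities."""

    condensed: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.condensed = np.asarray(self.condensed, dtype=float)
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if self.condensed.shape != (n * (n - 1) // 2,):
            raise ValueError("condensed length does not match the number of ids")
        if (self.condensed < -1e-12).any():
            raise ValueError("dissimilarities must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def square(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.condensed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.square(), index=self.ids, columns=self.ids)

    def save(self, path) -> None:
        """Persist condensed (np.savez: ids + condensed upper triangle)."""
        np.savez(path, ids=self.ids, condensed=self.condensed)

    @classmethod
    def load(cls, path) -> "DistanceMatrix":
        with np.load(path, allow_pickle=False) as data:
            return cls(condensed=data["condensed"], ids=data["ids"])


# ---------------------------------------------------------------------------
# transition rates and cost construction
# ---------------------------------------------------------------------------


def estimate_transition_rates(panel: SequencePanel) -> TransitionMatrix:
    """Pooled year-to-year transition rates ``p(j | i)``.

    Counts every adjacent observed pair ``(state at t, state at t+1)`` over
    all persons and ages; rows with no observed origin are set to the uniform
    distribution and flagged in ``unobserved_origins``.
    """
    if panel.n == 0:
        raise ValueError("empty panel")
    k = len(panel.alphabet)
    src = panel.codes[:, :-1].ravel()
    dst = panel.codes[:, 1:].ravel()
    ok = (src != MISSING) & (dst != MISSING)
    if not ok.any():
        raise ValueError("no adjacent observed state pairs in the panel")
    counts = np.zeros((k, k))
    np.add.at(counts, (src[ok], dst[ok]), 1.0)
    totals = counts.sum(axis=1)
    rates = np.empty_like(counts)
    unobserved = []
    for i in range(k):
        if totals[i] > 0:
            rates[i] = counts[i] / totals[i]
        else:
            rates[i] = 1.0 / k
            unobserved.append(i)
    return TransitionMatrix(
        rates=rates, alphabet=panel.alphabet, unobserved_origins=tuple(unobserved)
    )


def trate_costs(
    tm: TransitionMatrix, c: float = 2.0, indel: float = 1.0
) -> CostModel:
    """Transition-rate substitution costs ``sub(i,j) = c - p(j|i) - p(i|j)``.

    The standard TRATE construction: frequent transitions between two states
    make them cheap to substitute, rare transitions expensive (maximum ``c``
    when never observed in either direction).  Costs are clipped at zero.
    """
    if c <= 0:
        raise ValueError("cost constant c must be positive")
    p = tm.rates
    sub = c - p - p.T
    np.fill_diagonal(sub, 0.0)
    sub = np.clip(sub, 0.0, None)
    sub = (sub + sub.T) / 2.0  # numerically enforce symmetry
    return CostModel(indel=indel, sub=sub, alphabet=tm.alphabet)


def constant_costs(
    value: float, indel: float = 1.0, alphabet: tuple[str, ...] = STATES
) -> CostModel:
    """Flat substitution cost for every distinct state pair."""
    if value <= 0:
        raise ValueError("substitution cost must be positive")
    k = len(alphabet)
    sub = np.full((k, k), float(value))
    np.fill_diagonal(sub, 0.0)
    return CostModel(indel=indel, sub=sub, alphabet=alphabet)


# ---------------------------------------------------------------------------
# optimal matching
# ---------------------------------------------------------------------------


def om_distance(a, b, cm: CostModel) -> float:
    """OM edit distance between two sequences.

    ``a`` and ``b`` may be token lists or integer code arrays.  Standard
    ``(|a|+1) x (|b|+1)`` Needleman-Wunsch dynamic program over insert,
    delete (each ``cm.indel``) and substitute (``cm.sub``) operations.
    """
    a = _as_codes(a, cm.alphabet)
    b = _as_codes(b, cm.alphabet)
    la, lb = len(a), len(b)
    prev = np.arange(lb + 1, dtype=float) * cm.indel
    cur = np.empty(lb + 1)
    for i in range(1, la + 1):
        cur[0] = i * cm.indel
        subrow = cm.sub[a[i - 1]]
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j] + cm.indel,
                cur[j - 1] + cm.indel,
                prev[j - 1] + subrow[b[j - 1]],
            )
        prev, cur = cur, prev
    return float(prev[lb])


def _as_codes(seq, alphabet) -> np.ndarray:
    arr = np.asarray(seq)
    if arr.dtype.kind in "iu":
        if ((arr < 0) | (arr >= len(alphabet))).any():
            raise ValueError("sequence codes outside the alphabet")
        return arr.astype(np.int16)
    lookup = {s: i for i, s in enumerate(alphabet)}
    try:
        return np.array([lookup[s] for s in arr], dtype=np.int16)
    except KeyError as err:
        raise ValueError(f"unknown state token: {err.args[0]!r}") from None


@njit(cache=True)
def _om_pairs_kernel(codes, sub, indel):  # pragma: no cover - numba
    n, t = codes.shape
    out = np.empty(n * (n - 1) // 2)
    prev = np.empty(t + 1)
    cur = np.empty(t + 1)
    idx = 0
    for i in range(n - 1):
        a = codes[i]
        for j in range(i + 1, n):
            b = codes[j]
            for col in range(t + 1):
                prev[col] = col * indel
            for r in range(1, t + 1):
                cur[0] = r * indel
                ar = a[r - 1]
                for col in range(1, t + 1):
                    best = prev[col] + indel
                    alt = cur[col - 1] + indel
                    if alt < best:
                        best = alt
                    alt = prev[col - 1] + sub[ar, b[col - 1]]
                    if alt < best:
                        best = alt
                    cur[col] = best
                for col in range(t + 1):
                    prev[col] = cur[col]
            out[idx] = prev[t]
            idx += 1
    return out


def estimate_pairwise_memory(n: int) -> int:
    """Bytes needed for the condensed distance vector of an n-person panel."""
    return 8 * n * (n - 1) // 2


def pairwise_distances(
    panel: SequencePanel,
    cm: CostModel,
    dedupe: bool = True,
    memory_limit_bytes: int = 4 * 1024**3,
) -> DistanceMatrix:
    """All-pairs OM dissimilarities for a preprocessed panel.

    Identical sequences are detected first (``dedupe=True``) and each
    distinct pair is aligned only once; the result is bit-identical to the
    naive double loop.  Raises before allocation if the condensed matrix
    would exceed ``memory_limit_bytes``.
    """
    if panel.has_missing():
        raise ValueError("panel has missing states; call fill_gaps() first")
    n = panel.n
    need = estimate_pairwise_memory(n)
    if need > memory_limit_bytes:
        raise MemoryError(
            f"condensed distance matrix needs {need / 1e9:.1f} GB "
            f"(n={n}), above the configured limit"
        )
    codes = np.ascontiguousarray(panel.codes, dtype=np.int16)
    sub = np.ascontiguousarray(cm.sub, dtype=np.float64)
    if dedupe:
        uniq, inverse = np.unique(codes, axis=0, return_inverse=True)
        if uniq.shape[0] < n:
            du = _om_pairs_kernel(uniq, sub, float(cm.indel))
            usq = _condensed_to_square(du, uniq.shape[0])
            iu, ju = np.triu_indices(n, k=1)
            condensed = usq[inverse[iu], inverse[ju]]
            return DistanceMatrix(condensed=condensed, ids=panel.ids.copy())
    condensed = _om_pairs_kernel(codes, sub, float(cm.indel))
    return DistanceMatrix(condensed=condensed, ids=panel.ids.copy())


def _condensed_to_square(condensed: np.ndarray, n: int) -> np.ndarray:
    from scipy.spatial.distance import squareform

    if n == 1:
        return np.zeros((1, 1))
    return squareform(condensed)
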