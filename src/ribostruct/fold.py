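"""Nussinov-style RNA folding score.

Maximum-weight nested base pairing (GC=3, AU=2, GU=1, minimum hairpin loop
of 3 unpaired nt) computed by dynamic programming.  The negated pair weight
is exposed as a pseudo-energy on a kcal/mol-like scale so that synthetic
5'UTRs can be given internally consistent folding energies.  This is a
combinatorial scoring model, not a thermodynamic minimum-free-energy
predictor; measured folding-energy tables for real transcriptomes are
consumed unchanged by the structure-analysis layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


MIN_LOOP = 3  # minimum number of unpaired nucleotides enclosed by a pair

# nucleotide codes: A=0, C=1, G=2, U=3
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# symmetric pair-weight lookup, 0 = not pairable
_PAIR_WEIGHT = np.zeros((4, 4), dtype=np.int64)
_PAIR_WEIGHT[2, 1] = _PAIR_WEIGHT[1, 2] = 3  # G-C
_PAIR_WEIGHT[0, 3] = _PAIR_WEIGHT[3, 0] = 2  # A-U
_PAIR_WEIGHT[2, 3] = _PAIR_WEIGHT[3, 2] = 1  # G-U


class FoldError(ValueError):
    """Raised for sequences outside the {A,C,G,U,T} alphabet."""


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 codes (A=0, C=1, G=2, U/T=3)."""
    seq = sequence.upper()
    codes = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        try:
            codes[i] = _CODE[ch]
        except KeyError:
            raise FoldError(f"invalid nucleotide {ch!r} at position {i}") from None
    return codes


@njit(cache=True)
def _fill_dp(codes, weights, min_loop):  # pragma: no cover - numba kernel
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]  # j unpaired
            w = weights[codes[i], codes[j]]
            if w > 0:
                cand = w + (dp[i + 1, j - 1] if j - 1 >= i + 1 else 0)
                if cand > best:
                    best = cand
            # j pairs with interior k
            for k in range(i + 1, j - min_loop):
                w = weights[codes[k], codes[j]]
                if w > 0:
                    cand = dp[i, k - 1] + w
                    if k + 1 <= j - 1:
                        cand += dp[k + 1, j - 1]
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


@njit(cache=True)
def _traceback(dp, codes, weights, min_loop):  # pragma: no cover - numba kernel
    n = codes.shape[0]
    pairs = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return pairs
    stack_i = np.empty(2 * n + 2, dtype=np.int64)
    stack_j = np.empty(2 * n + 2, dtype=np.int64)
    top = 0
    stack_i[top] = 0
    stack_j[top] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        if i >= j or j - i <= min_loop:
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack_i[top] = i
            stack_j[top] = j - 1
            top += 1
            continue
        found = False
        w = weights[codes[i], codes[j]]
        if w > 0:
            inner = dp[i + 1, j - 1] if j - 1 >= i + 1 else 0
            if dp[i, j] == w + inner:
                pairs[i] = j
                pairs[j] = i
                stack_i[top] = i + 1
                stack_j[top] = j - 1
                top += 1
                found = True
        if not found:
            for k in range(i + 1, j - min_loop):
                w = weights[codes[k], codes[j]]
                if w == 0:
                    continue
                inner = dp[k + 1, j - 1] if k + 1 <= j - 1 else 0
                if dp[i, j] == dp[i, k - 1] + w + inner:
                    pairs[k] = j
                    pairs[j] = k
                    stack_i[top] = i
                    stack_j[top] = k - 1
                    top += 1
                    stack_i[top] = k + 1
                    stack_j[top] = j - 1
                    top += 1
                    break
    return pairs


@dataclass(frozen=True)
class FoldResult:
    """Maximum nested pair weight for one sequence.

    ``pairs`` maps each position to its partner (or -1 if unpaired) for one
    optimal structure; ``pseudo_energy`` is ``-1.0 * score``.
    """

    score: int
    pseudo_energy: float
    pairs: np.ndarray = field(repr=False)

    @property
    def paired_mask(self) -> np.ndarray:
        return self.pairs >= 0


def fold_score(sequence: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Score a sequence by maximum-weight nested base pairing.

    Parameters
    ----------
    sequence:
        RNA (or DNA) string over A/C/G/U/T, length >= 1.
    min_loop:
        Minimum number of unpaired nucleotides a pair must enclose.

    Returns
    -------
    FoldResult with the integer pair-weight score, the pseudo-energy
    (``-score``), and one optimal pairing.
    """
    if len(sequence) == 0:
        raise FoldError("sequence must be non-empty")
    codes = encode_sequence(sequence)
    n = codes.shape[0]
    if n <= min_loop + 1:
        return FoldResult(0, 0.0, np.full(n, -1, dtype=np.int64))
    dp = _fill_dp(codes, _PAIR_WEIGHT, min_loop)
    pairs = _traceback(dp, codes, _PAIR_WEIGHT, min_loop)
    score = int(dp[0, n - 1])
    return FoldResult(score, -1.0 * score, pairs)
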