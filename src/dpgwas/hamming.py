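"""Exact shortest Hamming distance to the significance boundary.

With the control row public and fixed, the space of genotype tables reachable
by re-genotyping case individuals is the integer triangle
``{(r0, r1) : r0, r1 >= 0, r0 + r1 <= R}``.  Re-genotyping one case moves the
table to a lattice neighbour: six legal moves, each changing the case
major-allele count ``x = 2 r0 + r1`` by -2, -1, +1 or +2.  Since the allelic
statistic depends on the case row only through ``x`` and is unimodal in it
(zero on the line ``x S = n10 R``, increasing away from it), the significant
region is the complement of an x-interval, and the shortest number of moves
to flip a table's significance status has a closed form.

The *Hamming distance score* of a table D at threshold c is

    h(D) = -(shortest distance)      if Y_A(D) <  c   (insignificant)
    h(D) = (shortest distance) - 1   if Y_A(D) >= c   (significant)

so h >= 0 exactly for significant tables.  When no table in the space is
significant, the distance for an insignificant table is defined as
1 + (moves to the nearer triangle corner (0,0) or (R,0)).  The score's
sensitivity — the largest |h(D) - h(D')| over one-move neighbours — is 1,
which is what makes it directly usable in the exponential mechanism; an
empirical auditor verifying this by enumeration is included.

A breadth-first-search oracle (:func:`shortest_hamming_bfs`) realises the
definition literally and serves as the independent correctness check for the
fast algorithm.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .tables import (
    DomainError,
    GenotypeTable,
    SignificanceThreshold,
    SnpPanel,
    chi2_profile,
)

#: the six legal one-record moves (dr0, dr1); dr2 = -(dr0 + dr1)
LEGAL_MOVES: tuple[tuple[int, int], ...] = (
    (+1, 0),
    (+1, -1),
    (0, -1),
    (-1, 0),
    (-1, +1),
    (0, +1),
)


class UnsupportedTableError(DomainError):
    """Monomorphic control row: the score's geometry is undefined."""


class UnreachableBoundaryError(DomainError):
    """No insignificant table exists in the space (c below min Y_A)."""


@dataclass(frozen=True)
class TableSpace:
    """All genotype tables sharing a control row and case total R."""

    s0: float
    s1: float
    s2: float
    R: int

    def __post_init__(self) -> None:
        if self.R < 1:
            raise DomainError("TableSpace requires R >= 1")
        if min(self.s0, self.s1, self.s2) < 0:
            raise DomainError("control counts must be non-negative")

    @property
    def S(self) -> float:
        return self.s0 + self.s1 + self.s2

    @property
    def N(self) -> float:
        return self.R + self.S

    @property
    def n10(self) -> float:
        """Control major-allele count 2 s0 + s1."""
        return 2 * self.s0 + self.s1

    @property
    def size(self) -> int:
        return (self.R + 1) * (self.R + 2) // 2

    def tables(self) -> Iterator[GenotypeTable]:
        """All (R+1)(R+2)/2 case rows, in lexicographic (r0, r1) order."""
        for r0 in range(self.R + 1):
            for r1 in range(self.R - r0 + 1):
                yield GenotypeTable(r0, r1, self.R - r0 - r1, self.s0, self.s1, self.s2)

    @classmethod
    def of(cls, t: GenotypeTable) -> "TableSpace":
        return cls(t.s0, t.s1, t.s2, t.R)


@dataclass(frozen=True)
class HammingResult:
    """Outcome of a shortest-distance computation for one table."""

    distance: int
    score: int
    significant: bool
    branch: str  # which walk attained the minimum: H1, H2, H1', H2'


def legal_moves(r0: int, r1: int, R: int) -> list[tuple[int, int]]:
    """The subset of the six one-record moves feasible at (r0, r1).

    Feasibility keeps all three case genotype classes non-negative: the move
    (+1, 0) converts an r2 individual to r0 so needs r0 + r1 < R; (-1, 0)
    converts r0 to r2; and so on.  Interior points admit all six.
    """
    if r0 < 0 or r1 < 0 or r0 + r1 > R:
        raise DomainError(f"invalid case row corner (r0={r0}, r1={r1}, R={R})")
    out = []
    for dr0, dr1 in LEGAL_MOVES:
        a, b = r0 + dr0, r1 + dr1
        if a >= 0 and b >= 0 and a + b <= R:
            out.append((dr0, dr1))
    return out


def _check_supported(t: GenotypeTable) -> None:
    n10 = 2 * t.s0 + t.s1
    if not (0 < n10 < 2 * t.S):
        raise UnsupportedTableError(
            "monomorphic control row: Hamming distance score undefined "
            f"(n10={n10}, 2S={2 * t.S})"
        )


def _steps_down(delta: int, r0: int) -> int:
    """Fewest moves lowering x by delta from a row with r0 homozygous-major.

    Each -2 move consumes one r0 record; -1 moves are always available while
    x > 0.  max(ceil(delta/2), delta - r0) is both achievable and a lower
    bound (each move lowers x by at most 2 and lowers x - r0 by at most 1).
    """
    return max(-(-delta // 2), delta - r0)


def _steps_up(delta: int, r2: int) -> int:
    """Fewest moves raising x by delta; mirror of _steps_down with r2 donors."""
    return max(-(-delta // 2), delta - r2)


def shortest_hamming_fast(t: GenotypeTable, thr: SignificanceThreshold) -> HammingResult:
    """Closed-form shortest Hamming distance to the significance boundary.

    For an insignificant table the two candidate walks move x down (H1) or up
    (H2) to the nearest significant x; if the whole space is insignificant,
    the fallback 1 + min(d1, d2) over the triangle corners applies.  For a
    significant table the single feasible walk moves x toward the zero line
    x = n10 R / S into the insignificant band; the opposite walk is infinite.
    """
    _check_supported(t)
    R = t.R
    a, b = t.r0, t.r1
    r2 = R - a - b
    x0 = 2 * a + b
    ys = chi2_profile(2 * t.s0 + t.s1, R, t.S)
    sig = ys >= thr.c
    significant = bool(sig[x0])

    if not significant:
        below = np.flatnonzero(sig[:x0])
        above = np.flatnonzero(sig[x0 + 1 :])
        h1 = _steps_down(x0 - int(below.max()), a) if below.size else None
        h2 = _steps_up(int(above.min()) + 1, r2) if above.size else None
        if h1 is None and h2 is None:
            # whole space insignificant: 1 + distance to the nearer corner
            d1 = a + b  # moves to (0, 0), i.e. x -> 0
            d2 = R - a  # moves to (R, 0), i.e. x -> 2R
            if d1 <= d2:
                dist, branch = 1 + d1, "H1'"
            else:
                dist, branch = 1 + d2, "H2'"
        elif h2 is None or (h1 is not None and h1 <= h2):
            dist, branch = h1, "H1"
        else:
            dist, branch = h2, "H2"
        return HammingResult(distance=dist, score=-dist, significant=False, branch=branch)

    insig = np.flatnonzero(~sig)
    if insig.size == 0:
        raise UnreachableBoundaryError(
            "every table in the space is significant; no boundary to cross"
        )
    lo, hi = int(insig.min()), int(insig.max())
    if x0 < lo:  # left shaded region: walk x upward toward the zero line
        dist, branch = _steps_up(lo - x0, r2), "H2"
    else:  # x0 > hi: right shaded region, walk x downward
        dist, branch = _steps_down(x0 - hi, a), "H1"
    return HammingResult(distance=dist, score=dist - 1, significant=True, branch=branch)


def shortest_hamming_bfs(t: GenotypeTable, thr: SignificanceThreshold) -> HammingResult:
    """Breadth-first-search oracle over the table space.

    Literal realisation of the definition: explore case rows outward from
    (r0, r1) one legal move at a time and return the depth of the first row
    whose significance status differs.  Intended for small R; the fast
    algorithm must agree with this everywhere.
    """
    _check_supported(t)
    R = t.R
    ys = chi2_profile(2 * t.s0 + t.s1, R, t.S)
    sig = ys >= thr.c
    start = (t.r0, t.r1)
    significant = bool(sig[2 * t.r0 + t.r1])

    dist = {start: 0}
    queue = deque([start])
    flipped_at = None
    while queue:
        (a, b) = queue.popleft()
        d = dist[(a, b)]
        if flipped_at is not None and d >= flipped_at:
            break
        for dr0, dr1 in legal_moves(a, b, R):
            nxt = (a + dr0, b + dr1)
            if nxt in dist:
                continue
            dist[nxt] = d + 1
            queue.append(nxt)
            if bool(sig[2 * nxt[0] + nxt[1]]) != significant and flipped_at is None:
                flipped_at = d + 1
    if flipped_at is not None:
        score = flipped_at - 1 if significant else -flipped_at
        return HammingResult(flipped_at, score, significant, branch="bfs")
    if significant:
        raise UnreachableBoundaryError(
            "every table in the space is significant; no boundary to cross"
        )
    # exhausted an all-insignificant space: BFS distances to the corners
    d1 = dist[(0, 0)]
    d2 = dist[(R, 0)]
    dmin = 1 + min(d1, d2)
    return HammingResult(dmin, -dmin, False, branch="H1'" if d1 <= d2 else "H2'")


def empirical_sensitivity(space: TableSpace, thr: SignificanceThreshold) -> int:
    """Max |h(D) - h(D')| over all one-move neighbour pairs, by enumeration.

    Audit of the score's sensitivity; returns exactly 1 whenever the
    significance boundary is crossable within the space.
    """
    scores: dict[tuple[int, int], int] = {}
    for t in space.tables():
        scores[(t.r0, t.r1)] = shortest_hamming_fast(t, thr).score
    worst = 0
    for (a, b), h in scores.items():
        for dr0, dr1 in legal_moves(a, b, space.R):
            worst = max(worst, abs(h - scores[(a + dr0, b + dr1)]))
    return worst


def empirical_chi2_sensitivity(space: TableSpace) -> float:
    """Max |Y_A(D) - Y_A(D')| over one-move neighbours of an enumerated space.

    Empirical counterpart of the chi-square score's sensitivity for users who
    must supply one to the Laplace/exponential mechanisms; exact for the given
    space, a lower bound for larger spaces.
    """
    ys = chi2_profile(space.n10, space.R, space.S)
    worst = 0.0
    for t in space.tables():
        x = 2 * t.r0 + t.r1
        for dr0, dr1 in legal_moves(t.r0, t.r1, space.R):
            worst = max(worst, abs(ys[x] - ys[x + 2 * dr0 + dr1]))
    return float(worst)


def panel_chi2_sensitivity(panel: SnpPanel) -> float:
    """Max one-move |ΔY_A| over every SNP's immediate neighbourhood.

    A panel-local empirical estimate (not a certified global bound) usable as
    the chi-square sensitivity in utility experiments.
    """
    worst = 0.0
    for snp_id, t in panel:
        n10 = 2 * t.s0 + t.s1
        if not (0 < n10 < 2 * t.S):
            continue
        ys = chi2_profile(n10, t.R, t.S)
        x = 2 * t.r0 + t.r1
        for dr0, dr1 in legal_moves(t.r0, t.r1, t.R):
            worst = max(worst, abs(ys[x] - ys[x + 2 * dr0 + dr1]))
    return float(worst)


def hamming_score_panel(panel: SnpPanel, thr: SignificanceThreshold) -> np.ndarray:
    """Hamming distance score for every SNP, in panel order."""
    out = np.empty(len(panel), dtype=int)
    for i, (snp_id, t) in enumerate(panel):
        try:
            out[i] = shortest_hamming_fast(t, thr).score
        except DomainError as exc:
            raise type(exc)(f"snp_id={snp_id!r}: {exc}") from exc
    return out
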