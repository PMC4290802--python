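"""Case-control contingency tables and the allelic association test.

A single SNP in a GWAS with ``R`` cases and ``S`` controls is summarised by a
2x3 *genotype table*: counts of individuals carrying 0, 1 or 2 copies of the
minor allele, split by case/control status.  Counting each individual's two
alleles separately collapses it to a 2x2 *allelic table* of minor/major
allele counts.  The allelic test statistic ``Y_A`` — the Pearson chi-square on
the allelic table, equivalent to the Cochran-Armitage trend test under the
additive model — measures the case/control association on 1 degree of
freedom:

    Y_A = 2N [(2 r0 + r1) S - (2 s0 + s1) R]^2
          / (R S (2 n0 + n1)(n1 + 2 n2))

with ``n_i = r_i + s_i`` and ``N = R + S``.  When the control group is
supplied as a minor-allele frequency instead of genotype counts, its genotype
row is derived under Hardy-Weinberg equilibrium, which may yield real-valued
control cells; only the case row must be integral.

This module also provides the one-parameter form ``Y_A(x)`` in the case
major-allele count ``x = 2 r0 + r1`` (controls held fixed), which underlies
the exact Hamming-distance score algorithm in :mod:`dpgwas.hamming`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("dpgwas")

#: absolute/relative tolerance for cross-formula chi-square equivalences
CHI2_EQUIV_TOL = 1e-9

#: tolerance on real-valued control rows summing to S
CONTROL_SUM_TOL = 1e-9


class DomainError(ValueError):
    """An input is outside the domain an operation is defined on."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeTable:
    """One SNP's 2x3 case/control genotype-count table.

    Case counts ``r0, r1, r2`` (by number of minor alleles) are non-negative
    integers; control counts ``s0, s1, s2`` may be non-negative reals, since
    a Hardy-Weinberg derivation from an allele frequency need not produce
    integers.
    """

    r0: int
    r1: int
    r2: int
    s0: float
    s1: float
    s2: float

    def __post_init__(self) -> None:
        for name in ("r0", "r1", "r2"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise DomainError(f"case count {name}={v!r} must be a non-negative integer")
            object.__setattr__(self, name, int(v))
        for name in ("s0", "s1", "s2"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"control count {name}={v!r} must be a non-negative real")
            object.__setattr__(self, name, v)

    @property
    def R(self) -> int:
        return self.r0 + self.r1 + self.r2

    @property
    def S(self) -> float:
        return self.s0 + self.s1 + self.s2

    @property
    def N(self) -> float:
        return self.R + self.S

    @property
    def case_row(self) -> tuple[int, int, int]:
        return (self.r0, self.r1, self.r2)

    @property
    def control_row(self) -> tuple[float, float, float]:
        return (self.s0, self.s1, self.s2)

    def with_case_row(self, r0: int, r1: int, r2: int) -> "GenotypeTable":
        """Same controls, different case row (a point in the table space)."""
        return GenotypeTable(r0, r1, r2, self.s0, self.s1, self.s2)


@dataclass(frozen=True)
class AllelicTable:
    """2x2 minor/major allele-count table derived from a genotype table."""

    case_minor: float
    case_major: float
    control_minor: float
    control_major: float

    def __post_init__(self) -> None:
        for name in ("case_minor", "case_major", "control_minor", "control_major"):
            if getattr(self, name) < 0:
                raise DomainError(f"allelic cell {name} must be non-negative")

    @property
    def case_total(self) -> float:
        return self.case_minor + self.case_major

    @property
    def control_total(self) -> float:
        return self.control_minor + self.control_major

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.case_minor, self.case_major], [self.control_minor, self.control_major]],
            dtype=float,
        )


@dataclass(frozen=True)
class SignificanceThreshold:
    """A p-value threshold ``p_star`` and its chi-square(1 df) critical value.

    ``c`` satisfies ``P(chi2_1 >= c) = p_star``; a table is *significant* when
    its allelic statistic is at least ``c`` (ties at ``c`` count as
    significant).
    """

    p_star: float
    c: float

    @classmethod
    def from_p(cls, p_star: float) -> "SignificanceThreshold":
        return chi2_threshold(p_star)


@dataclass
class SnpPanel:
    """Ordered collection of SNP genotype tables with unique identifiers.

    Panel order is stable and defines the tie-breaking rank used by the
    selection mechanisms.
    """

    snp_ids: list[str]
    tables: list[GenotypeTable]
    control_maf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(self.tables):
            raise DomainError("snp_ids and tables must have equal length")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise DomainError("snp_id values must be unique")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __iter__(self) -> Iterator[tuple[str, GenotypeTable]]:
        return iter(zip(self.snp_ids, self.tables))

    def table(self, snp_id: str) -> GenotypeTable:
        return self.tables[self.snp_ids.index(snp_id)]

    def chi2_scores(self) -> np.ndarray:
        """Allelic chi-square statistic for every SNP, in panel order."""
        return np.array([allelic_chi2(t) for t in self.tables], dtype=float)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def hwe_control_genotypes(maf: float, S: float) -> tuple[float, float, float]:
    """Expand a control minor-allele frequency into HWE genotype counts.

    Under Hardy-Weinberg equilibrium at allele frequency ``p``, the genotype
    proportions are (1-p)^2, 2p(1-p), p^2, so the expected control counts are

        s0 = S (1-maf)^2,  s1 = 2 S maf (1-maf),  s2 = S maf^2

    which sum to ``S`` analytically.
    """
    if not (0.0 <= maf <= 1.0):
        raise DomainError(f"minor-allele frequency {maf!r} must lie in [0, 1]")
    if S <= 0:
        raise DomainError(f"control total S={S!r} must be positive")
    q = 1.0 - maf
    return (S * q * q, 2.0 * S * maf * q, S * maf * maf)


def round_preserving_sum(counts: Sequence[float]) -> tuple[int, ...]:
    """Largest-remainder rounding of non-negative reals, preserving the sum.

    Optional helper for users who want integer control rows from an HWE
    derivation; the statistics and the Hamming algorithm do not require it.
    """
    floors = [math.floor(c) for c in counts]
    total = round(sum(counts))
    if not math.isclose(sum(counts), total, abs_tol=1e-6):
        raise DomainError("counts must sum to an integer to round without changing the total")
    remainders = sorted(
        range(len(counts)), key=lambda i: (-(counts[i] - floors[i]), i)
    )
    deficit = total - sum(floors)
    out = list(floors)
    for i in remainders[:deficit]:
        out[i] += 1
    return tuple(out)


def allelic_from_genotype(t: GenotypeTable) -> AllelicTable:
    """Collapse a 2x3 genotype table to its 2x2 allelic table.

    Each individual contributes two alleles: a heterozygote one of each, the
    homozygotes two of a kind.
    """
    return AllelicTable(
        case_minor=t.r1 + 2 * t.r2,
        case_major=2 * t.r0 + t.r1,
        control_minor=t.s1 + 2 * t.s2,
        control_major=2 * t.s0 + t.s1,
    )


def allelic_chi2(t: GenotypeTable) -> float:
    """The allelic test statistic Y_A of a genotype table.

    Returns 0 (with a logged warning) for monomorphic SNPs, where an allelic
    column margin vanishes and the usual statistic is 0/0; the numerator is
    then forced to zero as well, so 0 is the continuous completion.
    """
    R, S = t.R, t.S
    if R <= 0 or S <= 0:
        raise DomainError("allelic_chi2 requires R > 0 and S > 0")
    N = t.N
    n0 = t.r0 + t.s0
    n1 = t.r1 + t.s1
    n2 = t.r2 + t.s2
    major_margin = 2 * n0 + n1
    minor_margin = n1 + 2 * n2
    if major_margin == 0 or minor_margin == 0:
        logger.warning(
            "monomorphic table (zero allelic margin): returning Y_A = 0 by convention"
        )
        return 0.0
    num = 2.0 * N * ((2 * t.r0 + t.r1) * S - (2 * t.s0 + t.s1) * R) ** 2
    den = R * S * major_margin * minor_margin
    return num / den


def chi2_of_x(x: float, n10: float, R: float, S: float, N: float) -> float:
    """Y_A as a function of the case major-allele count ``x = 2 r0 + r1``.

    With the control row fixed (``n10 = 2 s0 + s1`` major alleles among
    controls), every genotype table sharing the same ``x`` has the same
    allelic statistic:

        Y_A(x) = 2N (x S - n10 R)^2 / (R S (x + n10)(2N - x - n10))

    The statistic vanishes on the line ``x S = n10 R`` (equal case/control
    major-allele frequencies) and, by unimodality, increases monotonically
    away from it on either side.
    """
    if not (0 <= x <= 2 * R):
        raise DomainError(f"x={x!r} must lie in [0, 2R]")
    if not (0 <= n10 <= 2 * S):
        raise DomainError(f"n10={n10!r} must lie in [0, 2S]")
    den = R * S * (x + n10) * (2 * N - x - n10)
    if den <= 0:
        raise DomainError("zero allelic margin: chi2_of_x undefined (monomorphic boundary)")
    return 2.0 * N * (x * S - n10 * R) ** 2 / den


def chi2_profile(n10: float, R: int, S: float) -> np.ndarray:
    """Vector of Y_A(x) for every integer x in [0, 2R] (fixed control row).

    Vectorised convenience used by the Hamming-score walks; requires
    ``0 < n10 < 2S`` so that every x on the grid has positive margins.
    """
    if not (0 < n10 < 2 * S):
        raise DomainError("chi2_profile requires a polymorphic control row (0 < n10 < 2S)")
    N = R + S
    x = np.arange(2 * R + 1, dtype=float)
    num = 2.0 * N * (x * S - n10 * R) ** 2
    den = R * S * (x + n10) * (2 * N - x - n10)
    return num / den


def chi2_threshold(p_star: float) -> SignificanceThreshold:
    """Critical value of the chi-square(1) distribution at upper-tail p_star."""
    if not (0.0 < p_star < 1.0):
        raise DomainError(f"p_star={p_star!r} must lie in (0, 1)")
    c = float(stats.chi2.isf(p_star, df=1))
    return SignificanceThreshold(p_star=p_star, c=c)


# ---------------------------------------------------------------------------
# Panel TSV I/O
# ---------------------------------------------------------------------------

_COUNT_COLS = ["r0", "r1", "r2"]
_CONTROL_COLS = ["s0", "s1", "s2"]


def _format_cell(v: float) -> str:
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


def read_panel(path: str | Path, n_controls: float | None = None) -> SnpPanel:
    """Read a panel TSV (columns: snp_id, r0, r1, r2, and either s0,s1,s2
    or control_maf).

    With the ``control_maf`` column, control genotype rows are derived under
    HWE; ``n_controls`` (the control sample size S) is then required.  Lines
    starting with '#' are ignored.  Invariant violations are reported with
    the offending 1-based line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str})
    missing = [c for c in ["snp_id", *_COUNT_COLS] if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing required columns {missing}")
    has_counts = all(c in df.columns for c in _CONTROL_COLS)
    has_maf = "control_maf" in df.columns
    if not has_counts and not has_maf:
        raise DomainError(f"{path}: need either s0,s1,s2 columns or a control_maf column")
    if has_maf and not has_counts and n_controls is None:
        raise DomainError(f"{path}: control_maf form requires n_controls (control sample size)")

    ids: list[str] = []
    tables: list[GenotypeTable] = []
    mafs: dict[str, float] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        lineno = pos + 2  # header is line 1
        try:
            if has_counts:
                s0, s1, s2 = (getattr(row, c) for c in _CONTROL_COLS)
            else:
                maf = float(row.control_maf)
                s0, s1, s2 = hwe_control_genotypes(maf, n_controls)
                mafs[row.snp_id] = maf
            t = GenotypeTable(row.r0, row.r1, row.r2, s0, s1, s2)
        except (DomainError, TypeError, ValueError) as exc:
            raise DomainError(f"{path}:{lineno}: invalid row for snp_id={row.snp_id!r}: {exc}") from exc
        ids.append(row.snp_id)
        tables.append(t)
    return SnpPanel(snp_ids=ids, tables=tables, control_maf=mafs)


def write_panel(
    panel: SnpPanel,
    path: str | Path,
    extra_columns: dict[str, Sequence] | None = None,
    provenance: str | None = None,
) -> None:
    """Write a panel TSV in the genotype-count dialect.

    ``extra_columns`` appends score columns (e.g. chi2, hamming_score) in
    panel order.  ``provenance`` emits a leading '#' comment line (skipped on
    read).  Integer-valued cells round-trip byte-identically.
    """
    path = Path(path)
    cols = ["snp_id", *_COUNT_COLS, *_CONTROL_COLS]
    extra = extra_columns or {}
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("\t".join(cols + list(extra)) + "\n")
        for i, (snp_id, t) in enumerate(panel):
            cells = [snp_id] + [
                _format_cell(v) for v in (t.r0, t.r1, t.r2, t.s0, t.s1, t.s2)
            ]
            cells += [_format_cell(extra[k][i]) if isinstance(extra[k][i], (int, float, np.floating, np.integer)) else str(extra[k][i]) for k in extra]
            fh.write("\t".join(cells) + "\n")


def read_score_column(path: str | Path, column: str) -> tuple[list[str], np.ndarray]:
    """Read snp_id plus one numeric score column from a scored panel TSV."""
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype={"snp_id": str})
    if column not in df.columns:
        raise DomainError(f"{path}: no column {column!r}")
    return list(df["snp_id"]), df[column].to_numpy(dtype=float)
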