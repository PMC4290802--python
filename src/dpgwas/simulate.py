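"""Synthetic case-control SNP panels.

The generator emulates the shape of a GWAS selection problem: M SNPs typed
in R cases and S controls.  Each SNP draws a population minor-allele
frequency from a uniform range (bounded away from 0 to honour the
common-SNP assumption, MAF > 1%); the *observed* control MAF is then a
binomial sample of 2S alleles at that frequency — control frequencies in a
real panel are themselves estimates from a finite public sample — and the
control genotype row is its Hardy-Weinberg expansion.  Case genotype rows
are drawn from an HWE trinomial at the population frequency, so under the
null both groups carry independent sampling noise and the allelic statistic
is calibrated to its chi-square(1) reference (mean ~ 1).  A chosen subset of
SNPs is truly associated: their case allele frequency is shifted by a fixed
effect, so a nontrivial top-K ranking exists and is recorded as ground
truth.

Defaults mirror a challenge-style panel: R=201 cases, S=174 controls, MAF
uniform on [0.05, 0.5].  One global seed expands into per-SNP substreams, so
increasing M extends a panel without reshuffling earlier SNPs.

Also provides purpose-built small panels for utility experiments: one where
the Hamming-score and chi-square rankings disagree, and one with strongly
separated Hamming scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .tables import (
    DomainError,
    GenotypeTable,
    SignificanceThreshold,
    SnpPanel,
    allelic_chi2,
    hwe_control_genotypes,
)
from .hamming import TableSpace


class SimulationError(DomainError):
    """Infeasible simulation specification."""


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic panel.

    effect is the absolute shift added to the control MAF to obtain the case
    MAF at associated SNPs (clipped into (0.01, 0.99)); null SNPs share the
    control MAF exactly.
    """

    M: int = 5000
    R: int = 201
    S: int = 174
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_assoc: int = 0
    effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise SimulationError(f"M={self.M} must be >= 1")
        if self.R < 1 or self.S < 1:
            raise SimulationError("R and S must be >= 1")
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise SimulationError(
                f"maf_range={self.maf_range} must satisfy 0.01 < lo <= hi <= 0.5 "
                "(common-SNP assumption)"
            )
        if not (0 <= self.n_assoc <= self.M):
            raise SimulationError(f"n_assoc={self.n_assoc} must lie in [0, M]")
        if not (0 <= self.effect < 1):
            raise SimulationError(f"effect={self.effect} must lie in [0, 1)")


@dataclass
class SimulatedPanel:
    """A synthetic panel plus its generating ground truth."""

    panel: SnpPanel
    truth: dict[str, dict] = field(default_factory=dict)

    @property
    def associated_ids(self) -> set[str]:
        return {k for k, v in self.truth.items() if v["associated"]}

    def write_truth(self, path: str | Path) -> None:
        with open(Path(path), "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=2)
            fh.write("\n")


def simulate_panel(spec: SimulationSpec) -> SimulatedPanel:
    """Generate a synthetic panel; deterministic given spec.seed.

    The first ``n_assoc`` SNPs (in panel order) are the associated ones;
    ids are zero-padded so panel order is also lexicographic.
    """
    width = max(5, len(str(spec.M - 1)))
    ids: list[str] = []
    tables: list[GenotypeTable] = []
    truth: dict[str, dict] = {}
    mafs: dict[str, float] = {}
    lo, hi = spec.maf_range
    for i in range(spec.M):
        rng = np.random.default_rng([spec.seed, i])
        p = float(rng.uniform(lo, hi))
        associated = i < spec.n_assoc
        p_case = float(np.clip(p + spec.effect, 0.01, 0.99)) if associated else p
        # observed control MAF: finite-sample estimate of p from 2S alleles,
        # clipped into the common-SNP band to keep allelic margins positive
        p_ctrl = float(
            np.clip(rng.binomial(2 * spec.S, p) / (2 * spec.S), 0.01, 0.99)
        )
        s0, s1, s2 = hwe_control_genotypes(p_ctrl, spec.S)
        probs = [(1 - p_case) ** 2, 2 * p_case * (1 - p_case), p_case**2]
        r0, r1, r2 = (int(v) for v in rng.multinomial(spec.R, probs))
        snp_id = f"snp{i:0{width}d}"
        t = GenotypeTable(r0, r1, r2, s0, s1, s2)
        ids.append(snp_id)
        tables.append(t)
        mafs[snp_id] = p_ctrl
        truth[snp_id] = {"associated": associated, "true_chi2": allelic_chi2(t)}
    panel = SnpPanel(snp_ids=ids, tables=tables, control_maf=mafs)
    return SimulatedPanel(panel=panel, truth=truth)


def enumerate_table_space(R: int, control_row: tuple[float, float, float]) -> Iterator[GenotypeTable]:
    """All (R+1)(R+2)/2 case rows over a fixed control row.

    Yields in lexicographic (r0, r1) order: r0 = 0..R outer, r1 = 0..R-r0
    inner.
    """
    if R < 1:
        raise SimulationError(f"R={R} must be >= 1")
    s0, s1, s2 = control_row
    return TableSpace(s0, s1, s2, R).tables()


# ---------------------------------------------------------------------------
# Purpose-built panels for utility experiments
# ---------------------------------------------------------------------------


def separated_panel(
    M: int = 40,
    n_assoc: int = 5,
    R: int = 200,
    S: int = 200,
    effect: float = 0.3,
    seed: int = 0,
) -> SimulatedPanel:
    """Panel whose associated SNPs have strongly separated Hamming scores.

    A large allele-frequency effect at moderate sample size pushes associated
    SNPs many record-changes beyond a genome-wide-style threshold while null
    SNPs sit far below it, so the integer Hamming scores split into two
    well-separated groups.  This is the regime where the exponential
    mechanism with the Hamming score excels at small privacy budgets.
    """
    return simulate_panel(
        SimulationSpec(M=M, R=R, S=S, n_assoc=n_assoc, effect=effect, seed=seed)
    )


def ranking_disagreement_panel(
    thr: SignificanceThreshold, K: int = 3, seed: int = 0
) -> SimulatedPanel:
    """Small panel on which the Hamming top-K and the chi-square top-K differ.

    Construction: significant SNPs whose chi-square order and
    distance-to-boundary order are deliberately discordant.  ``shallow_hot``
    has the largest statistic of the panel, but its rarer control allele
    squeezes the minor-allele margin so the significance boundary sits only a
    few record changes away (small Hamming score); the ``deep_*`` SNPs have
    slightly smaller statistics but common alleles, leaving many
    boundary-crossing moves (larger Hamming scores).  As the budget grows,
    the Hamming-score mechanism converges to *its* top-K, which is not the
    chi-square top-K that utility is measured against — the utility plateau.

    Designed for K=3 at thresholds near p* = 0.1/M (M=8); deterministic, the
    ``seed`` argument is accepted for interface uniformity only.
    """
    R, S = 60, 60
    ids: list[str] = []
    tables: list[GenotypeTable] = []
    truth: dict[str, dict] = {}

    def add(snp_id: str, r0: int, r1: int, maf: float, associated: bool) -> None:
        s0, s1, s2 = hwe_control_genotypes(maf, S)
        t = GenotypeTable(r0, r1, R - r0 - r1, s0, s1, s2)
        ids.append(snp_id)
        tables.append(t)
        truth[snp_id] = {"associated": associated, "true_chi2": allelic_chi2(t)}

    # Significant and far from the boundary in Hamming steps (common allele).
    add("deep_a", 44, 14, 0.45, True)
    add("deep_b", 45, 11, 0.45, True)
    add("deep_c", 43, 14, 0.45, True)
    # Largest chi-square of the panel, but a rarer control allele puts the
    # boundary within a few record changes (small Hamming score).
    add("shallow_hot", 60, 0, 0.20, True)
    # Clearly null background.
    add("null_a", 20, 28, 0.45, False)
    add("null_b", 19, 30, 0.45, False)
    add("null_c", 21, 27, 0.45, False)
    add("null_d", 20, 29, 0.45, False)
    return SimulatedPanel(
        panel=SnpPanel(snp_ids=ids, tables=tables), truth=truth
    )
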