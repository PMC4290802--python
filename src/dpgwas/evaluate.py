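"""Utility metric and risk-utility sweeps.

Utility of a private release is the fraction of the true top-K SNPs — ranked
by their unperturbed allelic chi-square statistics — that the mechanism
recovered:  u = |S0 ∩ S| / |S0|.  A sweep runs each mechanism over a grid of
privacy budgets (and, for the Hamming score, significance thresholds),
repeating each cell with derived seeds and reporting mean and standard
deviation of utility.  The qualitative expectations: chi-square-score
mechanisms improve monotonically with the budget and reach utility 1;
the Hamming-score mechanism can dominate at small budgets but plateau below
1 when its ranking disagrees with the chi-square ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables import DomainError, SnpPanel, chi2_threshold
from .hamming import hamming_score_panel
from .mechanisms import ConfigError, MechanismConfig, release

#: mechanism/score combinations a sweep understands
SWEEP_MECHANISMS = ("laplace-chi2", "exponential-chi2", "exponential-hamming")


@dataclass(frozen=True)
class SweepGrid:
    """Grid of sweep parameters.

    Defaults mirror a challenge-style experiment: budgets spanning 1..50,
    a few release sizes, and thresholds of 0.1 and 0.01 divided by the
    number of SNPs (supplied per panel via p_stars).
    """

    epsilons: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
    Ks: tuple[int, ...] = (3, 5, 10)
    p_stars: tuple[float, ...] = ()
    repetitions: int = 200
    base_seed: int = 0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.epsilons):
            raise ConfigError("all epsilons must be positive")
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        if any(k < 1 for k in self.Ks):
            raise ConfigError("all Ks must be >= 1")


def utility(true_top: Iterable[str], released: Iterable[str]) -> float:
    """|S0 ∩ S| / |S0| for two equal-size top-K sets."""
    s0, s = set(true_top), set(released)
    if len(s0) != len(s) or not s0:
        raise DomainError(
            f"utility needs equal non-empty set sizes, got {len(s0)} and {len(s)}"
        )
    return len(s0 & s) / len(s0)


def true_top_k(panel: SnpPanel, K: int) -> set[str]:
    """The K SNPs with the largest allelic chi-square; ties break by
    ascending panel index."""
    if K > len(panel):
        raise DomainError(f"K={K} exceeds panel size {len(panel)}")
    scores = panel.chi2_scores()
    order = np.argsort(-scores, kind="stable")[:K]
    return {panel.snp_ids[i] for i in order}


def _cell_seed(base_seed: int, cell: int, rep: int) -> int:
    """Deterministic per-repetition seed, independent of sweep iteration order."""
    ss = np.random.SeedSequence([base_seed, cell, rep])
    return int(ss.generate_state(1)[0] % (2**31))


def risk_utility_sweep(
    panel: SnpPanel,
    grid: SweepGrid,
    mechanisms: Sequence[str] = SWEEP_MECHANISMS,
    chi2_sensitivity: float | None = None,
) -> pd.DataFrame:
    """Mean/sd utility for every (mechanism, epsilon, K[, p*]) grid cell.

    chi-square-score mechanisms need an explicit sensitivity;
    the Hamming-score mechanism needs at least one threshold in
    ``grid.p_stars`` and uses sensitivity 1.  Rows are sorted
    deterministically.
    """
    for m in mechanisms:
        if m not in SWEEP_MECHANISMS:
            raise ConfigError(f"unknown sweep mechanism {m!r}")
    if any(m.endswith("chi2") for m in mechanisms) and chi2_sensitivity is None:
        raise ConfigError("chi2-score mechanisms require chi2_sensitivity")
    if any(m.endswith("hamming") for m in mechanisms) and not grid.p_stars:
        raise ConfigError("hamming-score mechanisms require grid.p_stars")

    chi2_scores = panel.chi2_scores()
    hamming_scores = {
        p: hamming_score_panel(panel, chi2_threshold(p)) for p in grid.p_stars
    }
    rows = []
    cell = 0
    for mech in sorted(mechanisms):
        mech_name, score_kind = mech.rsplit("-", 1)
        p_grid: tuple[float | None, ...] = (
            grid.p_stars if score_kind == "hamming" else (None,)
        )
        for K in grid.Ks:
            truth = true_top_k(panel, K)
            for eps in grid.epsilons:
                for p_star in p_grid:
                    if score_kind == "hamming":
                        scores = hamming_scores[p_star]
                        sens: float | None = 1.0
                    else:
                        scores = chi2_scores
                        sens = chi2_sensitivity
                    utils = np.empty(grid.repetitions)
                    for rep in range(grid.repetitions):
                        config = MechanismConfig(
                            epsilon=eps,
                            K=K,
                            score_kind=score_kind,
                            sensitivity=sens,
                            p_star=p_star,
                            seed=_cell_seed(grid.base_seed, cell, rep),
                        )
                        result = release(scores, config, mech_name, panel.snp_ids)
                        utils[rep] = utility(truth, result.selected)
                    rows.append(
                        {
                            "mechanism": mech,
                            "epsilon": eps,
                            "K": K,
                            "p_star": np.nan if p_star is None else p_star,
                            "mean_utility": utils.mean(),
                            "sd_utility": utils.std(ddof=1) if grid.repetitions > 1 else 0.0,
                            "reps": grid.repetitions,
                            "seed": grid.base_seed,
                        }
                    )
                    cell += 1
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["mechanism", "K", "p_star", "epsilon"], na_position="first"
    ).reset_index(drop=True)


def write_sweep(df: pd.DataFrame, path: str | Path, provenance: str | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def plot_sweep(df: pd.DataFrame, path: str | Path) -> None:
    """Optional risk-utility figure: one panel per (K, p*), utility vs eps.

    Cosmetic companion to the numeric table; requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Ks = sorted(df["K"].unique())
    p_stars = sorted(df["p_star"].dropna().unique()) or [np.nan]
    fig, axes = plt.subplots(
        len(Ks), len(p_stars), figsize=(4.2 * len(p_stars), 3.2 * len(Ks)),
        squeeze=False, sharey=True,
    )
    for i, K in enumerate(Ks):
        for j, p_star in enumerate(p_stars):
            ax = axes[i][j]
            sub = df[df["K"] == K]
            for mech, g in sub.groupby("mechanism"):
                if mech.endswith("hamming"):
                    g = g[np.isclose(g["p_star"], p_star)]
                g = g.sort_values("epsilon")
                if g.empty:
                    continue
                ax.errorbar(
                    g["epsilon"], g["mean_utility"], yerr=g["sd_utility"],
                    marker="o", capsize=2, label=mech,
                )
            ax.set_xscale("log")
            ax.set_ylim(-0.05, 1.05)
            title = f"K={K}"
            if not np.isnan(p_star):
                title += f", p*={p_star:.2g}"
            ax.set_title(title)
            if i == len(Ks) - 1:
                ax.set_xlabel("privacy budget ε")
            if j == 0:
                ax.set_ylabel("utility u(ε)")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
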