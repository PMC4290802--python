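"""Differentially private top-K selection mechanisms.

Two standard building blocks, extended to release K SNPs out of M under a
total privacy budget epsilon:

* **Laplace top-K** — add i.i.d. Laplace(0, 2Ks/eps) noise to every SNP's
  score (s = score sensitivity) and release the K largest perturbed scores.
* **Exponential top-K** — draw K SNPs sequentially without replacement, each
  draw picking SNP i with probability proportional to exp(eps * q_i / (2Ks));
  a selected SNP's weight is set to exactly 0 for later draws.

Either mechanism works with any score; here the scores of interest are the
allelic chi-square statistic (sensitivity supplied by the user, e.g. from an
empirical audit) and the Hamming distance score (sensitivity 1 by
construction).  All randomness flows from the integer seed in the config, so
releases are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .tables import DomainError

SCORE_KINDS = ("chi2", "hamming")


class ConfigError(DomainError):
    """Invalid mechanism configuration."""


@dataclass(frozen=True)
class MechanismConfig:
    """Configuration shared by both release mechanisms.

    ``sensitivity`` must be given explicitly for chi-square scores (there is
    no safe default); it defaults to 1 for Hamming scores.  ``p_star`` is the
    significance threshold the Hamming scores were computed at and is
    required metadata for that score kind.
    """

    epsilon: float
    K: int
    score_kind: str
    sensitivity: float | None = None
    p_star: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ConfigError(f"epsilon={self.epsilon!r} must be positive")
        if self.K < 1:
            raise ConfigError(f"K={self.K!r} must be at least 1")
        if self.score_kind not in SCORE_KINDS:
            raise ConfigError(f"score_kind={self.score_kind!r} not in {SCORE_KINDS}")
        if self.score_kind == "hamming":
            if self.sensitivity is None:
                object.__setattr__(self, "sensitivity", 1.0)
            if self.p_star is None:
                raise ConfigError("score_kind='hamming' requires p_star")
        elif self.sensitivity is None:
            raise ConfigError(
                "score_kind='chi2' requires an explicit sensitivity "
                "(see dpgwas.hamming.empirical_chi2_sensitivity for an audit)"
            )
        if self.sensitivity <= 0:
            raise ConfigError(f"sensitivity={self.sensitivity!r} must be positive")

    def noise_scale(self) -> float:
        """Laplace scale / exponential denominator: 2 K s / eps."""
        return 2.0 * self.K * self.sensitivity / self.epsilon

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ReleaseResult:
    """K selected SNP identifiers, in selection order, plus provenance.

    Raw per-SNP scores are retained in memory for diagnostics but omitted
    from serialised output by default — they are not differentially private
    outputs themselves.
    """

    selected: list[str]
    mechanism: str
    config: MechanismConfig
    scores: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ConfigError("selected SNP ids must be unique")

    def write(self, prefix: str | Path, include_scores: bool = False) -> None:
        """Write <prefix>.tsv (rank, snp_id) and a <prefix>.json sidecar."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".tsv"), "w", encoding="utf-8") as fh:
            fh.write("rank\tsnp_id\n")
            for rank, snp_id in enumerate(self.selected, start=1):
                fh.write(f"{rank}\t{snp_id}\n")
        sidecar = {
            "mechanism": self.mechanism,
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
        }
        if include_scores and self.scores is not None:
            import logging

            logging.getLogger("dpgwas").warning(
                "serialising raw per-SNP scores: these are NOT privacy-protected"
            )
            sidecar["scores"] = list(map(float, self.scores))
        with open(prefix.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2)
            fh.write("\n")


def _as_ids(scores: np.ndarray, snp_ids: Sequence[str] | None) -> list[str]:
    if snp_ids is None:
        return [str(i) for i in range(len(scores))]
    if len(snp_ids) != len(scores):
        raise ConfigError("snp_ids and scores length mismatch")
    return list(snp_ids)


def _validate(scores: np.ndarray, config: MechanismConfig) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size == 0:
        raise ConfigError("scores must be a non-empty 1-d array")
    if not np.all(np.isfinite(scores)):
        raise ConfigError("scores must be finite")
    if config.K > scores.size:
        raise ConfigError(f"K={config.K} exceeds panel size M={scores.size}")
    return scores


def laplace_top_k(
    scores: Sequence[float],
    config: MechanismConfig,
    snp_ids: Sequence[str] | None = None,
) -> ReleaseResult:
    """Release the K SNPs with the largest Laplace-perturbed scores.

    Noise is i.i.d. Laplace(0, 2Ks/eps) per SNP.  Ties on perturbed scores
    (probability zero for continuous noise) break by ascending panel index.
    """
    scores = _validate(scores, config)
    ids = _as_ids(scores, snp_ids)
    rng = np.random.default_rng(config.seed)
    perturbed = scores + rng.laplace(0.0, config.noise_scale(), size=scores.size)
    order = np.argsort(-perturbed, kind="stable")[: config.K]
    return ReleaseResult(
        selected=[ids[i] for i in order],
        mechanism="laplace",
        config=config,
        scores=scores,
    )


def _softmax_weights(scores: np.ndarray, active: np.ndarray, scale: float) -> np.ndarray:
    """exp(q_i / scale) over the active set, normalised; overflow-safe."""
    w = np.zeros_like(scores)
    act = scores[active] / scale
    act = np.exp(act - act.max())
    w[active] = act / act.sum()
    return w


def exponential_top_k(
    scores: Sequence[float],
    config: MechanismConfig,
    snp_ids: Sequence[str] | None = None,
) -> ReleaseResult:
    """Release K SNPs by sequential exponential-mechanism draws.

    Each draw selects from the not-yet-released SNPs with probability
    proportional to exp(eps * q_i / (2Ks)); released SNPs get weight exactly
    0 (never a large negative score, avoiding NaN arithmetic).
    """
    scores = _validate(scores, config)
    ids = _as_ids(scores, snp_ids)
    rng = np.random.default_rng(config.seed)
    scale = config.noise_scale()
    active = np.ones(scores.size, dtype=bool)
    selected: list[str] = []
    for _ in range(config.K):
        probs = _softmax_weights(scores, active, scale)
        j = int(rng.choice(scores.size, p=probs))
        selected.append(ids[j])
        active[j] = False
    return ReleaseResult(
        selected=selected, mechanism="exponential", config=config, scores=scores
    )


def selection_probabilities(
    scores: Sequence[float], config: MechanismConfig
) -> np.ndarray:
    """Exact single-draw (K=1) selection probabilities of the exponential
    mechanism: softmax of eps*q/(2s), computed after subtracting the maximum
    exponent for overflow safety.  Sums to 1 within 1e-12.
    """
    if config.K != 1:
        raise ConfigError("selection_probabilities is defined for K=1")
    scores = _validate(scores, config)
    return _softmax_weights(scores, np.ones(scores.size, dtype=bool), config.noise_scale())


def release(
    scores: Sequence[float],
    config: MechanismConfig,
    mechanism: str,
    snp_ids: Sequence[str] | None = None,
) -> ReleaseResult:
    """Dispatch on mechanism name ('laplace' or 'exponential')."""
    if mechanism == "laplace":
        return laplace_top_k(scores, config, snp_ids)
    if mechanism == "exponential":
        return exponential_top_k(scores, config, snp_ids)
    raise ConfigError(f"unknown mechanism {mechanism!r}")
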