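"""Configuration for the synthetic-data generator.

A single :class:`SimConfig` drives every generator so that one seed fixes
the full set of pipeline inputs bit-for-bit.  The defaults describe the
study conditions the package is benchmarked under: a scaled-down gene
universe with 35 planted pathogenic genes, twelve ranked-list sources of
heterogeneous coverage, a protein-interaction network with nine planted
clique communities, and five differential-expression studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


class InvalidConfigError(ValueError):
    """Raised when a SimConfig violates one of its invariants."""


@dataclass
class SimConfig:
    # ranked-list generator
    n_genes: int = 2000
    n_positives: int = 35
    n_methods: int = 12
    coverage_pos: float = 0.9
    coverage_neg: float = 0.5
    #: shape of the positives' latent-quality Beta(a, 1); ``math.inf`` pins
    #: every positive's quality at 1 (the zero-noise limit used in tests).
    signal_a: float = 4.0
    noise_sd: float = 0.2

    # network generator
    n_communities: int = 9
    community_size: int = 10
    community_overlap: int = 2
    background_edge_prob: float = 0.005
    n_network_extra: int = 100
    intra_score_low: int = 900
    intra_score_high: int = 1000
    background_score_low: int = 150
    background_score_high: int = 899

    # microarray generator
    n_studies: int = 5
    n_de_genes: int = 300
    study_inclusion_prob: float = 0.6
    sign_flip_prob: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = {
            "coverage_pos": self.coverage_pos,
            "coverage_neg": self.coverage_neg,
            "background_edge_prob": self.background_edge_prob,
            "study_inclusion_prob": self.study_inclusion_prob,
            "sign_flip_prob": self.sign_flip_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name}={p} must lie in [0, 1]")
        if self.n_positives >= self.n_genes:
            raise InvalidConfigError(
                f"n_positives={self.n_positives} must be < n_genes={self.n_genes}"
            )
        if self.n_positives < 1 or self.n_methods < 1:
            raise InvalidConfigError("n_positives and n_methods must be >= 1")
        if self.community_size < 3:
            raise InvalidConfigError("community_size must be >= 3")
        if self.community_overlap >= self.community_size:
            raise InvalidConfigError(
                f"community_overlap={self.community_overlap} must be < "
                f"community_size={self.community_size}"
            )
        if self.community_overlap < 0 or self.n_communities < 1:
            raise InvalidConfigError("need community_overlap >= 0, n_communities >= 1")
        if not (self.signal_a > 0 or math.isinf(self.signal_a)):
            raise InvalidConfigError("signal_a must be positive (or inf)")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if not (0 < self.intra_score_low <= self.intra_score_high <= 1000):
            raise InvalidConfigError("intra-community score range invalid")
        if not (0 <= self.background_score_low <= self.background_score_high <= 1000):
            raise InvalidConfigError("background score range invalid")
        if self.n_de_genes > self.n_genes:
            raise InvalidConfigError("n_de_genes must be <= n_genes")
        if self.n_studies < 1:
            raise InvalidConfigError("n_studies must be >= 1")

    def gene_universe(self) -> list[str]:
        """Zero-padded Entrez-like identifiers for the whole gene universe."""
        return [f"{i:06d}" for i in range(1, self.n_genes + 1)]

    def to_dict(self) -> dict:
        return asdict(self)
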