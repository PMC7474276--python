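"""Run configuration shared by the pipeline stages.

The defaults are the published operating point of the method: 1000 bp
promoters, motif indexes of the top n = 5000 promoters, at most k = 5
binding sites per promoter, an information-content cutoff of 4 bits for
overlap removal, and significance at Bonferroni-corrected P < 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace


def _default_excluded() -> list[str]:
    # common names for organellar sequences in plant genome annotations
    return ["Mt", "Pt", "ChrM", "ChrC", "MT", "mitochondria", "chloroplast", "plastid"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters controlling promoter extraction, scanning and testing.

    Attributes
    ----------
    promoter_length:
        Upstream window taken from each transcription start site (bp).
    n:
        Number of top-scoring promoters per motif kept in the index.
    max_k:
        Largest number of non-overlapping hits considered per promoter.
    ic_cutoff:
        Overlaps whose information content exceeds this many bits on either
        motif trigger hit removal.
    alpha:
        Significance level applied to Bonferroni-adjusted p-values.
    background:
        ``"uniform"`` or ``"promoters"`` (0-order composition of the scanned
        promoter set).
    pseudocount:
        Additive pseudocount used when converting frequencies to log-odds
        for scanning (never applied to information content).
    both_strands:
        Scan the reverse strand with the reverse-complement motif.
    trials:
        ``"scanned"`` sets the binomial trial count to the number of
        candidate placements actually scanned, ``(L - w + 1) × strands``;
        an integer fixes it (e.g. 1000 for a literal 1-kb reading).
    granularity:
        Bin width (log-odds units) of the discretized null score
        distribution.
    score_floor:
        Per-position log-odds are clamped below at this value so that a
        zero frequency with zero pseudocount stays finite.
    """

    promoter_length: int = 1000
    n: int = 5000
    max_k: int = 5
    ic_cutoff: float = 4.0
    alpha: float = 0.05
    background: str = "uniform"
    pseudocount: float = 0.001
    both_strands: bool = True
    trials: int | str = "scanned"
    granularity: float = 1e-3
    score_floor: float = -32.0
    include_self_pairs: bool = False
    seed: int = 0
    excluded_seqids: list[str] = field(default_factory=_default_excluded)

    def __post_init__(self) -> None:
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 1 <= self.max_k:
            raise ValueError("max_k must be >= 1")
        if self.granularity <= 0:
            raise ValueError("granularity must be > 0")
        if isinstance(self.trials, str) and self.trials != "scanned":
            raise ValueError("trials must be an integer or 'scanned'")
        if self.background not in ("uniform", "promoters"):
            raise ValueError("background must be 'uniform' or 'promoters'")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def parameter_hash(self) -> str:
        """Stable digest of the scan-relevant parameters.

        The seed is excluded: it only affects synthetic data generation,
        not how a given input is scored.
        """
        payload = self.to_dict()
        payload.pop("seed", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
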