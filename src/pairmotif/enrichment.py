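"""Motif-pair colocalization and gene-set enrichment testing.

For a pair of motifs and a promoter present in both motif indexes,
overlaps between the recorded hits are found and judged by the
information content (IC) of the overlapping motif positions: if either
motif's IC over the overlap exceeds the cutoff (4 bits), both
participating hits are removed and the binomial scores are recomputed
from the remaining hits.  The pair is colocalized in the promoter when
both recomputed scores still pass the motifs' recorded index thresholds.
Gene sets are then tested for over-representation of pair-positive
promoters with an upper-tail hypergeometric test, Bonferroni-corrected
per gene set over the number of pairs tested.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from pairmotif.motifs import Motif, interval_ic
from pairmotif.scan import (
    Hit,
    MotifIndex,
    PromoterMotifScore,
    binomial_promoter_score,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapRecord:
    """One intersecting pair of hits with motif-local overlap positions."""

    hit_a: Hit
    hit_b: Hit
    positions_a: frozenset[int]
    positions_b: frozenset[int]
    ic_a: float
    ic_b: float


@dataclass(frozen=True)
class ColocalizationRecord:
    gene_id: str
    motif_a: str
    motif_b: str
    removed_hits: tuple[Hit, ...]
    rescored_a: float
    rescored_b: float
    colocalized: bool


@dataclass(frozen=True)
class GeneSet:
    """A named, optionally ranked gene list (most significant first)."""

    name: str
    gene_ids: tuple[str, ...]
    ranked: bool = True

    def __post_init__(self) -> None:
        ids = tuple(self.gene_ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"gene set {self.name!r} contains duplicate ids")
        object.__setattr__(self, "gene_ids", ids)

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> "GeneSet":
        if k < self.size and not self.ranked:
            raise ValueError(
                f"gene set {self.name!r} must be ranked to be truncated to its "
                f"top {k} genes"
            )
        return GeneSet(self.name, self.gene_ids[:k], ranked=self.ranked)


@dataclass(frozen=True)
class PairEnrichmentResult:
    motif_a: str
    motif_b: str
    universe_size: int
    pair_positive_universe: int
    set_size: int
    pair_positive_in_set: int
    raw_p: float
    adj_p: float

    def __post_init__(self) -> None:
        if self.pair_positive_in_set > min(self.set_size, self.pair_positive_universe):
            raise ValueError("pair_positive_in_set exceeds set or universe positives")


def _local_positions(hit: Hit, genomic_positions: Iterable[int]) -> frozenset[int]:
    """Map genomic overlap positions into motif-local indices.

    A minus-strand hit was scored with the reverse-complement matrix, so
    motif position i sits at genomic coordinate end-1-i.
    """
    if hit.strand == "+":
        return frozenset(g - hit.start for g in genomic_positions)
    return frozenset(hit.end - 1 - g for g in genomic_positions)


def find_overlaps(
    hits_a: Sequence[Hit],
    hits_b: Sequence[Hit],
    motif_a: Motif,
    motif_b: Motif,
) -> list[OverlapRecord]:
    """All intersecting (hit_a, hit_b) pairs with their overlap ICs."""
    records = []
    for ha in hits_a:
        for hb in hits_b:
            lo, hi = max(ha.start, hb.start), min(ha.end, hb.end)
            if lo >= hi:
                continue
            genomic = range(lo, hi)
            pos_a = _local_positions(ha, genomic)
            pos_b = _local_positions(hb, genomic)
            records.append(
                OverlapRecord(
                    hit_a=ha,
                    hit_b=hb,
                    positions_a=pos_a,
                    positions_b=pos_b,
                    ic_a=interval_ic(motif_a, pos_a),
                    ic_b=interval_ic(motif_b, pos_b),
                )
            )
    return records


def resolve_overlaps(
    records: Sequence[OverlapRecord],
    score_a: PromoterMotifScore,
    score_b: PromoterMotifScore,
    ic_cutoff: float = 4.0,
) -> tuple[list[Hit], list[Hit], float, float]:
    """Remove high-IC overlaps and rescore both motifs.

    Every overlap whose IC strictly exceeds ``ic_cutoff`` on either motif
    removes BOTH participating hits; an overlap at exactly the cutoff is
    retained.  The decision depends only on the IC, never on the overlap
    length.  Binomial scores are recomputed from the remaining hits with k
    re-optimized and the trial count unchanged; a motif left hitless
    rescores to 1.
    """
    removed_a = {r.hit_a for r in records if r.ic_a > ic_cutoff or r.ic_b > ic_cutoff}
    removed_b = {r.hit_b for r in records if r.ic_a > ic_cutoff or r.ic_b > ic_cutoff}
    retained_a = [h for h in score_a.selected_hits if h not in removed_a]
    retained_b = [h for h in score_b.selected_hits if h not in removed_b]
    if removed_a or removed_b:
        rescored_a = _rescore(score_a, retained_a)
        rescored_b = _rescore(score_b, retained_b)
    else:
        rescored_a = score_a.binom_score
        rescored_b = score_b.binom_score
    return retained_a, retained_b, rescored_a, rescored_b


def _rescore(original: PromoterMotifScore, retained: Sequence[Hit]) -> float:
    return binomial_promoter_score(
        retained,
        promoter_length=0,  # unused: trials carried over from the original
        motif_width=0,
        trials=original.trials,
        gene_id=original.gene_id,
        motif_id=original.motif_id,
    ).binom_score


def colocalization_test(
    gene_id: str,
    index_a: MotifIndex,
    index_b: MotifIndex,
    motif_a: Motif,
    motif_b: Motif,
    ic_cutoff: float = 4.0,
) -> ColocalizationRecord:
    """Decide whether two motifs colocalize in one promoter.

    The gene must be a member of both indexes.  The pair colocalizes when
    both overlap-resolved binomial scores are still at or below the
    motifs' recorded thresholds.
    """
    if gene_id not in index_a or gene_id not in index_b:
        raise KeyError(f"gene {gene_id!r} is not a member of both motif indexes")
    score_a = index_a.scores[gene_id]
    score_b = index_b.scores[gene_id]
    records = find_overlaps(
        score_a.selected_hits, score_b.selected_hits, motif_a, motif_b
    )
    retained_a, retained_b, rescored_a, rescored_b = resolve_overlaps(
        records, score_a, score_b, ic_cutoff
    )
    removed = tuple(
        h for h in (*score_a.selected_hits, *score_b.selected_hits)
        if h not in set(retained_a) | set(retained_b)
    )
    return ColocalizationRecord(
        gene_id=gene_id,
        motif_a=score_a.motif_id,
        motif_b=score_b.motif_id,
        removed_hits=removed,
        rescored_a=rescored_a,
        rescored_b=rescored_b,
        colocalized=bool(
            rescored_a <= index_a.threshold and rescored_b <= index_b.threshold
        ),
    )


def pair_positive_genes(
    index_a: MotifIndex,
    index_b: MotifIndex,
    motif_a: Motif,
    motif_b: Motif,
    ic_cutoff: float = 4.0,
) -> set[str]:
    """Genes in whose promoters the two motifs colocalize."""
    positives = set()
    for gene_id in sorted(index_a.member_genes & index_b.member_genes):
        score_a = index_a.scores[gene_id]
        score_b = index_b.scores[gene_id]
        # fast path: hits of equal-width lists overlap iff starts are close
        if not _any_interval_overlap(score_a.selected_hits, score_b.selected_hits):
            positives.add(gene_id)
            continue
        rec = colocalization_test(
            gene_id, index_a, index_b, motif_a, motif_b, ic_cutoff
        )
        if rec.colocalized:
            positives.add(gene_id)
    return positives


def _any_interval_overlap(hits_a: Sequence[Hit], hits_b: Sequence[Hit]) -> bool:
    return any(
        ha.start < hb.end and hb.start < ha.end
        for ha in hits_a
        for hb in hits_b
    )


def hypergeometric_pair_test(
    pair_positive_universe: int,
    universe_size: int,
    set_size: int,
    pair_positive_in_set: int,
) -> float:
    """Upper-tail hypergeometric p-value P(X >= observed).

    X counts pair-positive promoters in a draw of ``set_size`` genes from
    a universe containing ``pair_positive_universe`` positives.  An
    observed count of 0 gives p = 1.
    """
    if not 0 <= pair_positive_universe <= universe_size:
        raise ValueError("pair_positive_universe outside [0, universe_size]")
    if not 0 <= set_size <= universe_size:
        raise ValueError("set_size outside [0, universe_size]")
    if not 0 <= pair_positive_in_set <= min(set_size, pair_positive_universe):
        raise ValueError("observed count inconsistent with the other counts")
    if pair_positive_in_set == 0:
        return 1.0
    return float(
        hypergeom.sf(
            pair_positive_in_set - 1,
            universe_size,
            pair_positive_universe,
            set_size,
        )
    )


def bonferroni_adjust(raw_p: float, m: int) -> float:
    """min(1, raw_p * m) for m pairs tested."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, raw_p * m)


def equalize_gene_sets(sets: Sequence[GeneSet]) -> list[GeneSet]:
    """Truncate every set to the size of the smallest (top genes kept).

    Sets larger than the minimum must be ranked; equal-size inputs are
    returned unchanged.
    """
    if not sets:
        return []
    k = min(s.size for s in sets)
    return [s.top(k) for s in sets]


def test_gene_sets(
    pair_positives: Mapping[tuple[str, str], set[str]],
    universe_ids: Iterable[str],
    gene_sets: Sequence[GeneSet],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every motif pair in every gene set.

    ``pair_positives`` maps (motif_a, motif_b) to the colocalized gene
    set over the whole universe.  Genes absent from the universe are
    dropped from each gene set (with a logged count).  Bonferroni's m is
    the number of pairs tested, computed per gene set.  Rows are sorted by
    (gene_set, adj_p, raw_p, motif_a, motif_b).
    """
    universe = set(universe_ids)
    rows = []
    for gene_set in gene_sets:
        members = [g for g in gene_set.gene_ids if g in universe]
        dropped = gene_set.size - len(members)
        if dropped:
            logger.info(
                "gene set %r: %d of %d genes not in the promoter universe; dropped",
                gene_set.name, dropped, gene_set.size,
            )
        member_set = set(members)
        m = len(pair_positives)
        if m == 0:
            continue
        for (motif_a, motif_b), positives in pair_positives.items():
            observed = len(positives & member_set)
            raw = hypergeometric_pair_test(
                len(positives), len(universe), len(members), observed
            )
            adj = bonferroni_adjust(raw, m)
            rows.append(
                {
                    "gene_set": gene_set.name,
                    "motif_a": motif_a,
                    "motif_b": motif_b,
                    "universe_size": len(universe),
                    "pair_positive_universe": len(positives),
                    "set_size": len(members),
                    "dropped_genes": dropped,
                    "pair_positive_in_set": observed,
                    "raw_p": raw,
                    "adj_p": adj,
                    "significant": adj < alpha,
                    "m_pairs": m,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["gene_set", "adj_p", "raw_p", "motif_a", "motif_b"],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def all_motif_pairs(
    motif_ids: Sequence[str], include_self: bool = False
) -> list[tuple[str, str]]:
    """Unordered pairs of distinct motifs (optionally homotypic pairs)."""
    pairs = list(itertools.combinations(motif_ids, 2))
    if include_self:
        pairs += [(m, m) for m in motif_ids]
    return pairs


def pair_matrix(
    results: pd.DataFrame | Sequence[PairEnrichmentResult],
    motif_order: Sequence[str],
) -> pd.DataFrame:
    """Square matrix of -log10(adjusted p), symmetric, NaN when untested."""
    if isinstance(results, pd.DataFrame):
        triples = list(
            zip(results["motif_a"], results["motif_b"], results["adj_p"])
        )
    else:
        triples = [(r.motif_a, r.motif_b, r.adj_p) for r in results]
    order = list(motif_order)
    known = set(order)
    mat = pd.DataFrame(np.nan, index=order, columns=order)
    for a, b, adj in triples:
        if a not in known or b not in known:
            missing = a if a not in known else b
            raise ValueError(f"motif {missing!r} absent from motif_order")
        value = -math.log10(adj) if adj > 0 else math.inf
        mat.loc[a, b] = value
        mat.loc[b, a] = value
    return mat


def write_pair_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6f", na_rep="NA")


def read_pair_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


# ---------------------------------------------------------------------------
# gene-set file IO


def load_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Load a gene set from one-ID-per-line text or two-column TSV.

    In the two-column form the second column is a significance statistic;
    genes are ranked by ascending value (most significant first), ties by
    input order.  The one-column form is taken as already ranked.
    """
    path = Path(path)
    name = name or path.stem
    ids: list[str] = []
    stats: list[float] = []
    two_col = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        ids.append(fields[0])
        if len(fields) > 1:
            two_col = True
            stats.append(float(fields[1]))
        elif two_col:
            raise ValueError(f"{path}: inconsistent column counts")
    if two_col:
        order = np.argsort(np.array(stats), kind="stable")
        ids = [ids[i] for i in order]
    return GeneSet(name, tuple(ids), ranked=True)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_set.gene_ids))
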