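"""Motif scanning, binomial promoter scores, and per-motif indexes.

Scanning mirrors FIMO: every window on both strands gets a log-odds score
against a 0-order background, and the match p-value is the tail
probability of that score under an exact dynamic-programming null
distribution (per-position score distributions convolved on a discretized
grid).  Promoter-level presence of a motif is then scored with a binomial
model of site multiplicity: with p the geometric mean of the k best
non-overlapping hit p-values, the promoter score is P(X >= k) for
X ~ Binomial(N, p), minimized over 1 <= k <= 5, where N is the number of
candidate placements scanned.  For each motif the n best-scoring promoters
form its index, and the n-th score is recorded as the motif's threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from pairmotif.config import RunConfig
from pairmotif.motifs import Background, Motif, reverse_complement_motif
from pairmotif.promoters import Promoter, PromoterUniverse

# integer score assigned to each N (or padding) base in a window; one of
# these drives the window total far below the attainable minimum, so the
# looked-up p-value is 1
_N_SENTINEL = -(1 << 24)


@dataclass(frozen=True, slots=True)
class Hit:
    """One scored placement of a motif on a promoter."""

    motif_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float

    def overlaps(self, other: "Hit") -> bool:
        """Strand-agnostic interval intersection test."""
        return self.start < other.end and other.start < self.end

    def sort_key(self) -> tuple:
        return (self.pvalue, self.start, 0 if self.strand == "+" else 1)


@dataclass(frozen=True, slots=True)
class PromoterMotifScore:
    """Selected hits and the binomial score for one (motif, promoter)."""

    gene_id: str
    motif_id: str
    selected_hits: tuple[Hit, ...]
    geom_mean_p: float
    k_star: int
    trials: int
    binom_score: float


@dataclass(frozen=True)
class MotifIndex:
    """The n best-scoring promoters for one motif and the n-th score.

    ``scores`` maps member gene -> PromoterMotifScore, ordered by rank
    (ascending binomial score, ties broken by gene id).
    """

    motif_id: str
    n: int
    threshold: float
    scores: dict[str, PromoterMotifScore]

    @property
    def member_genes(self) -> set[str]:
        return set(self.scores)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.scores


class ScoreDistribution:
    """Exact discretized null distribution of a motif's log-odds score.

    Per-position log-odds (with an additive pseudocount, clamped below at
    ``score_floor``) are rounded to multiples of ``granularity`` and the
    per-position score distributions under the background are convolved.
    ``tail[j]`` is P(score >= min_score + j) on the integer grid.
    """

    def __init__(
        self,
        motif: Motif,
        background: Background,
        granularity: float = 1e-3,
        pseudocount: float = 0.001,
        score_floor: float = -32.0,
    ):
        if granularity <= 0:
            raise ValueError("granularity must be > 0")
        bg = background.freq
        adjusted = (motif.matrix + pseudocount * bg) / (1.0 + pseudocount)
        with np.errstate(divide="ignore"):
            lodds = np.log2(adjusted / bg)
        lodds = np.maximum(lodds, score_floor)
        iscores = np.rint(lodds / granularity).astype(np.int64)  # (w, 4)

        self.motif = motif
        self.granularity = float(granularity)
        # column 4 handles N / padding
        self.lut = np.concatenate(
            [iscores, np.full((motif.width, 1), _N_SENTINEL, dtype=np.int64)],
            axis=1,
        )
        mins = iscores.min(axis=1)
        self.min_score = int(mins.sum())
        self.max_score = int(iscores.max(axis=1).sum())

        dist = np.ones(1)
        for i in range(motif.width):
            rel = iscores[i] - mins[i]
            new = np.zeros(dist.size + int(rel.max()))
            for b in range(4):
                new[rel[b] : rel[b] + dist.size] += bg[b] * dist
            dist = new
        tail = np.cumsum(dist[::-1])[::-1]
        self.tail = np.minimum(tail, 1.0)

    def pvalues(self, iscores: np.ndarray) -> np.ndarray:
        """Tail probabilities P(score >= s) for integer window scores."""
        iscores = np.asarray(iscores)
        idx = iscores - self.min_score
        out = np.ones(iscores.shape, dtype=float)
        valid = idx >= 0
        if np.any(valid):
            clipped = np.minimum(idx[valid], self.tail.size - 1)
            out[valid] = self.tail[clipped]
        return out

    def window_iscores(self, encoded: np.ndarray) -> np.ndarray:
        """Integer scores of all windows of an encoded sequence (1D or 2D).

        For a 2D input of shape (genes, length) the result has shape
        (genes, length - width + 1); windows overhanging a promoter into
        padding score as non-matches.
        """
        encoded = np.atleast_2d(encoded)
        w = self.motif.width
        n_windows = encoded.shape[1] - w + 1
        if n_windows <= 0:
            return np.zeros((encoded.shape[0], 0), dtype=np.int64)
        total = self.lut[0][encoded[:, :n_windows]]
        for i in range(1, w):
            total = total + self.lut[i][encoded[:, i : i + n_windows]]
        return total

    def tail_probability(self, score: float) -> float:
        """P(score' >= score) with the score given in log-odds units."""
        iscore = int(np.rint(score / self.granularity))
        return float(self.pvalues(np.array([iscore]))[0])


def score_distribution(
    motif: Motif,
    background: Background,
    granularity: float = 1e-3,
    pseudocount: float = 0.001,
    score_floor: float = -32.0,
) -> ScoreDistribution:
    """Build the exact null score distribution for a motif."""
    return ScoreDistribution(motif, background, granularity, pseudocount, score_floor)


def _strand_distributions(
    motif: Motif, background: Background, config: RunConfig
) -> tuple[ScoreDistribution, ScoreDistribution | None]:
    fwd = ScoreDistribution(
        motif, background, config.granularity, config.pseudocount, config.score_floor
    )
    if not config.both_strands:
        return fwd, None
    rev = ScoreDistribution(
        reverse_complement_motif(motif),
        background,
        config.granularity,
        config.pseudocount,
        config.score_floor,
    )
    return fwd, rev


def scan_promoter(
    motif: Motif,
    promoter: Promoter,
    background: Background,
    config: RunConfig | None = None,
) -> list[Hit]:
    """All candidate placements of a motif on a promoter, best p first.

    One candidate per (position, strand); the minus strand is scored with
    the reverse-complement motif at the same forward coordinates.  Windows
    containing N score p-value 1.  An empty list is returned when the
    promoter is shorter than the motif.  Ties are broken by start, then
    strand (+ before -).
    """
    config = config or RunConfig()
    if promoter.length < motif.width:
        return []
    fwd, rev = _strand_distributions(motif, background, config)
    enc = promoter.encoded()[None, :]
    hits: list[Hit] = []
    for dist, strand in ((fwd, "+"), (rev, "-")):
        if dist is None:
            continue
        iscores = dist.window_iscores(enc)[0]
        pvals = dist.pvalues(iscores)
        for start in range(iscores.size):
            hits.append(
                Hit(
                    motif_id=motif.motif_id,
                    gene_id=promoter.gene_id,
                    start=start,
                    end=start + motif.width,
                    strand=strand,
                    score=float(iscores[start] * dist.granularity),
                    pvalue=float(pvals[start]),
                )
            )
    hits.sort(key=Hit.sort_key)
    return hits


def select_top_nonoverlapping(hits: Sequence[Hit], max_k: int = 5) -> list[Hit]:
    """Greedy selection of the best non-overlapping hits.

    Hits are taken in ascending p-value order (ties: start, then strand);
    a hit whose interval intersects an already-selected hit is discarded,
    irrespective of strand.  At most ``max_k`` hits are returned.
    """
    if max_k < 0:
        raise ValueError("max_k must be >= 0")
    ordered = sorted(hits, key=Hit.sort_key)
    selected: list[Hit] = []
    for hit in ordered:
        if len(selected) >= max_k:
            break
        if all(not hit.overlaps(s) for s in selected):
            selected.append(hit)
    return selected


def _n_trials(
    promoter_length: int,
    motif_width: int,
    both_strands: bool,
    trials: int | str = "scanned",
) -> int:
    if isinstance(trials, int):
        return trials
    n_positions = max(0, promoter_length - motif_width + 1)
    return n_positions * (2 if both_strands else 1)


def binomial_promoter_score(
    selected: Sequence[Hit],
    promoter_length: int,
    motif_width: int,
    both_strands: bool = True,
    trials: int | str = "scanned",
    gene_id: str | None = None,
    motif_id: str | None = None,
) -> PromoterMotifScore:
    """Binomial multiplicity score from the selected non-overlapping hits.

    For each k, p_k is the geometric mean of the k best hit p-values and
    score_k = P(X >= k), X ~ Binomial(N, p_k); the smallest score wins
    (smallest k on ties).  With no selected hits (or a promoter shorter
    than the motif) the score is 1 and k* = 0.
    """
    n = _n_trials(promoter_length, motif_width, both_strands, trials)
    gene_id = gene_id if gene_id is not None else (selected[0].gene_id if selected else "")
    motif_id = motif_id if motif_id is not None else (selected[0].motif_id if selected else "")
    ordered = sorted(selected, key=Hit.sort_key)
    if not ordered or n < 1:
        return PromoterMotifScore(gene_id, motif_id, tuple(ordered), 1.0, 0, n, 1.0)
    logs = np.log([h.pvalue for h in ordered])
    ks = np.arange(1, len(ordered) + 1)
    geo = np.exp(np.cumsum(logs) / ks)
    scores = binom.sf(ks - 1, n, geo)
    usable = ks <= n
    scores = np.where(usable, scores, np.inf)
    best = int(np.argmin(scores))
    return PromoterMotifScore(
        gene_id=gene_id,
        motif_id=motif_id,
        selected_hits=tuple(ordered),
        geom_mean_p=float(geo[best]),
        k_star=int(ks[best]),
        trials=n,
        binom_score=float(scores[best]),
    )


def score_promoter(
    motif: Motif,
    promoter: Promoter,
    background: Background,
    config: RunConfig | None = None,
) -> PromoterMotifScore:
    """Scan, select and score one (motif, promoter) pair."""
    config = config or RunConfig()
    hits = scan_promoter(motif, promoter, background, config)
    selected = select_top_nonoverlapping(hits, config.max_k)
    return binomial_promoter_score(
        selected,
        promoter.length,
        motif.width,
        both_strands=config.both_strands,
        trials=config.trials,
        gene_id=promoter.gene_id,
        motif_id=motif.motif_id,
    )


def build_motif_index(
    scores: Iterable[PromoterMotifScore] | Mapping[str, PromoterMotifScore],
    n: int = 5000,
) -> MotifIndex:
    """Keep the n smallest binomial scores; record the n-th as threshold.

    Ties at the boundary are broken by gene id, so the index is
    reproducible.  If the universe has at most n promoters, all of them
    are members.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(scores, Mapping):
        scores = scores.values()
    ranked = sorted(scores, key=lambda s: (s.binom_score, s.gene_id))
    if not ranked:
        raise ValueError("cannot build an index from zero promoter scores")
    motif_ids = {s.motif_id for s in ranked}
    if len(motif_ids) != 1:
        raise ValueError(f"scores mix motifs: {sorted(motif_ids)}")
    members = ranked[:n]
    return MotifIndex(
        motif_id=members[0].motif_id,
        n=n,
        threshold=members[-1].binom_score,
        scores={s.gene_id: s for s in members},
    )


# ---------------------------------------------------------------------------
# vectorized universe scoring


def _greedy_select_arrays(
    pvals: np.ndarray,
    starts: np.ndarray,
    strands: np.ndarray,
    width: int,
    max_k: int,
) -> list[int]:
    """Greedy non-overlap selection over candidate arrays.

    Returns indices into the candidate arrays in selection order.  The
    global candidate order is (p, start, strand); only a prefix of that
    order is materialized, growing until max_k hits are selected or the
    candidates are exhausted.  All hit intervals share the motif width,
    so two hits overlap iff |start_a - start_b| < width.
    """
    m = pvals.size
    if m == 0 or max_k == 0:
        return []
    target = min(8 * max_k, m)
    while True:
        if target >= m:
            sub = np.arange(m)
        else:
            cutoff = np.partition(pvals, target - 1)[target - 1]
            sub = np.nonzero(pvals <= cutoff)[0]
        order = sub[np.lexsort((strands[sub], starts[sub], pvals[sub]))]
        selected: list[int] = []
        sel_starts: list[int] = []
        for idx in order:
            s = starts[idx]
            if all(abs(s - t) >= width for t in sel_starts):
                selected.append(int(idx))
                sel_starts.append(int(s))
                if len(selected) >= max_k:
                    return selected
        if sub.size >= m:
            return selected
        target *= 4


def _score_universe_arrays(
    motif: Motif,
    universe: PromoterUniverse,
    background: Background,
    config: RunConfig,
) -> tuple[list[str], np.ndarray, list[list[Hit]], np.ndarray, np.ndarray, np.ndarray]:
    """Score every promoter for one motif (vectorized core).

    Returns gene ids, binomial scores, per-gene selected hits, k*, geometric
    mean p, and trial counts, all aligned with the universe order.
    """
    enc, lengths, ids = universe.encoded_matrix()
    w = motif.width
    fwd, rev = _strand_distributions(motif, background, config)

    per_gene_hits: list[list[Hit]] = []
    n_genes = len(ids)
    max_k = config.max_k
    sel_p = np.ones((n_genes, max_k))
    counts = np.zeros(n_genes, dtype=int)
    trials = np.array(
        [
            _n_trials(int(L), w, config.both_strands, config.trials)
            for L in lengths
        ],
        dtype=int,
    )

    n_windows = enc.shape[1] - w + 1
    if n_windows > 0:
        iscore_f = fwd.window_iscores(enc)
        pv_f = fwd.pvalues(iscore_f)
        if rev is not None:
            iscore_r = rev.window_iscores(enc)
            pv_r = rev.pvalues(iscore_r)
    for g in range(n_genes):
        valid = max(0, int(lengths[g]) - w + 1)
        if valid == 0:
            per_gene_hits.append([])
            continue
        if rev is not None:
            pv = np.concatenate([pv_f[g, :valid], pv_r[g, :valid]])
            isc = np.concatenate([iscore_f[g, :valid], iscore_r[g, :valid]])
            starts = np.concatenate([np.arange(valid)] * 2)
            strands = np.concatenate(
                [np.zeros(valid, dtype=np.int8), np.ones(valid, dtype=np.int8)]
            )
        else:
            pv, isc = pv_f[g, :valid], iscore_f[g, :valid]
            starts = np.arange(valid)
            strands = np.zeros(valid, dtype=np.int8)
        chosen = _greedy_select_arrays(pv, starts, strands, w, max_k)
        hits = [
            Hit(
                motif_id=motif.motif_id,
                gene_id=ids[g],
                start=int(starts[i]),
                end=int(starts[i]) + w,
                strand="+" if strands[i] == 0 else "-",
                score=float(isc[i] * fwd.granularity),
                pvalue=float(pv[i]),
            )
            for i in chosen
        ]
        per_gene_hits.append(hits)
        counts[g] = len(hits)
        sel_p[g, : len(hits)] = [h.pvalue for h in hits]

    # vectorized binomial scoring across all genes
    ks = np.arange(1, max_k + 1)
    with np.errstate(divide="ignore"):
        geo = np.exp(np.cumsum(np.log(sel_p), axis=1) / ks)
    sc = binom.sf(ks - 1, trials[:, None], geo)
    invalid = (ks[None, :] > counts[:, None]) | (ks[None, :] > trials[:, None])
    sc = np.where(invalid, np.inf, sc)
    any_valid = counts > 0
    kstar = np.zeros(n_genes, dtype=int)
    best = np.ones(n_genes)
    geo_best = np.ones(n_genes)
    if np.any(any_valid):
        arg = np.argmin(sc[any_valid], axis=1)
        kstar[any_valid] = arg + 1
        rows = np.nonzero(any_valid)[0]
        best[any_valid] = sc[rows, arg]
        geo_best[any_valid] = geo[rows, arg]
    return ids, best, per_gene_hits, kstar, geo_best, trials


def score_universe(
    motif: Motif,
    universe: PromoterUniverse,
    background: Background,
    config: RunConfig | None = None,
) -> dict[str, PromoterMotifScore]:
    """PromoterMotifScore for every promoter in the universe (one motif)."""
    config = config or RunConfig()
    ids, best, hits, kstar, geo, trials = _score_universe_arrays(
        motif, universe, background, config
    )
    return {
        gid: PromoterMotifScore(
            gene_id=gid,
            motif_id=motif.motif_id,
            selected_hits=tuple(hits[g]),
            geom_mean_p=float(geo[g]) if kstar[g] > 0 else 1.0,
            k_star=int(kstar[g]),
            trials=int(trials[g]),
            binom_score=float(best[g]),
        )
        for g, gid in enumerate(ids)
    }


def index_universe(
    motifs: Sequence[Motif],
    universe: PromoterUniverse,
    background: Background | None = None,
    config: RunConfig | None = None,
) -> dict[str, MotifIndex]:
    """Build the per-motif promoter indexes for a motif library.

    Only index members keep their PromoterMotifScore objects; the rest of
    the universe contributes through the rank cutoff and threshold.
    """
    config = config or RunConfig()
    if background is None:
        background = (
            Background(universe.base_composition())
            if config.background == "promoters"
            else Background.uniform()
        )
    seen: set[str] = set()
    for motif in motifs:
        if motif.motif_id in seen:
            raise ValueError(f"duplicate motif id {motif.motif_id!r}")
        seen.add(motif.motif_id)

    indexes: dict[str, MotifIndex] = {}
    for motif in motifs:
        ids, best, hits, kstar, geo, trials = _score_universe_arrays(
            motif, universe, background, config
        )
        ids_arr = np.asarray(ids)
        order = np.lexsort((ids_arr, best))
        members = order[: config.n]
        scores = {}
        for g in members:
            gid = ids[g]
            scores[gid] = PromoterMotifScore(
                gene_id=gid,
                motif_id=motif.motif_id,
                selected_hits=tuple(hits[g]),
                geom_mean_p=float(geo[g]) if kstar[g] > 0 else 1.0,
                k_star=int(kstar[g]),
                trials=int(trials[g]),
                binom_score=float(best[g]),
            )
        indexes[motif.motif_id] = MotifIndex(
            motif_id=motif.motif_id,
            n=config.n,
            threshold=float(best[members[-1]]),
            scores=scores,
        )
    return indexes


# ---------------------------------------------------------------------------
# index serialization (TSV per motif + JSON sidecar)


def _format_hits(hits: Sequence[Hit]) -> str:
    return ",".join(
        f"{h.start}:{h.end}:{h.strand}:{h.pvalue:.10g}" for h in hits
    )


def _parse_hits(text: str, motif_id: str, gene_id: str) -> tuple[Hit, ...]:
    if not text:
        return ()
    hits = []
    for token in text.split(","):
        start, end, strand, pval = token.split(":")
        hits.append(
            Hit(
                motif_id=motif_id,
                gene_id=gene_id,
                start=int(start),
                end=int(end),
                strand=strand,
                score=0.0,
                pvalue=float(pval),
            )
        )
    return tuple(hits)


def write_motif_index(index: MotifIndex, directory: str | Path,
                      parameters: dict | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tsv = directory / f"{index.motif_id}.index.tsv"
    with open(tsv, "w") as fh:
        fh.write("gene_id\tk_star\tgeom_mean_p\tbinom_score\ttrials\thits\n")
        for s in index.scores.values():
            fh.write(
                f"{s.gene_id}\t{s.k_star}\t{s.geom_mean_p:.10g}\t"
                f"{s.binom_score:.10g}\t{s.trials}\t{_format_hits(s.selected_hits)}\n"
            )
    sidecar = {
        "motif_id": index.motif_id,
        "n": index.n,
        "threshold": index.threshold,
        "members": len(index.scores),
        "parameters": parameters or {},
    }
    (directory / f"{index.motif_id}.index.json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1) + "\n"
    )


def read_motif_index(directory: str | Path, motif_id: str) -> MotifIndex:
    directory = Path(directory)
    meta = json.loads((directory / f"{motif_id}.index.json").read_text())
    scores: dict[str, PromoterMotifScore] = {}
    with open(directory / f"{motif_id}.index.tsv") as fh:
        header = fh.readline()
        assert header.startswith("gene_id"), "malformed index TSV"
        for line in fh:
            gid, k_star, geom_p, score, trials, hits = line.rstrip("\n").split("\t")
            scores[gid] = PromoterMotifScore(
                gene_id=gid,
                motif_id=motif_id,
                selected_hits=_parse_hits(hits, motif_id, gid),
                geom_mean_p=float(geom_p),
                k_star=int(k_star),
                trials=int(trials),
                binom_score=float(score),
            )
    return MotifIndex(
        motif_id=motif_id,
        n=int(meta["n"]),
        threshold=float(meta["threshold"]),
        scores=scores,
    )
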