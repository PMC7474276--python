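"""Synthetic promoter universes with planted motif pairs.

The generator emulates the genome-scale inputs of the pipeline at desk
scale: i.i.d. background promoters of configurable composition and
length, a library of random letter-probability motifs, a designated motif
pair planted together in a subset of promoters, and a gene set enriched
for those pair-positive promoters.  Everything is driven by a single seed
and is byte-reproducible.

Default plan values restate the benchmark world: a universe of 5000
promoters of 1000 bp, two width-8 motifs planted together in 200
promoters, and a gene set of 300 genes of which half carry the pair.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from pairmotif.motifs import ALPHABET, Background, Motif, write_meme_file
from pairmotif.promoters import Promoter, PromoterUniverse


@dataclass(frozen=True)
class PlantingPlan:
    """Declarative description of a synthetic benchmark world.

    ``n_motifs`` counts the whole library; the first ``planted_motifs``
    of them are planted together (as a pair for the default 2) in
    ``planted_promoters`` randomly chosen promoters,
    ``instances_per_promoter`` instances of each per promoter.
    ``overlap_bp > 0`` forces each planted A/B instance pair to intersect
    by that many bp.  ``index_n`` is the motif-index size a scaled-down
    universe is meant to be analyzed with (top 20% of the universe, the
    same proportion as 5000 of the ~27k nuclear gene promoters in the
    published genome-scale setting).
    """

    n_promoters: int = 5000
    promoter_length: int = 1000
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_motifs: int = 80
    motif_width: int = 8
    dominant_freq: float = 0.92
    planted_motifs: int = 2
    planted_promoters: int = 200
    instances_per_promoter: int = 2
    strand_policy: str = "both"
    overlap_bp: int = 0
    consensus_only: bool = False
    gene_set_size: int = 300
    pair_positive_fraction: float = 0.5
    index_n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pair_positive_fraction <= 1.0:
            raise ValueError("pair_positive_fraction must be in [0, 1]")
        if self.strand_policy not in ("+", "-", "both"):
            raise ValueError("strand_policy must be '+', '-' or 'both'")
        if self.planted_promoters > self.n_promoters:
            raise ValueError("more planted promoters than promoters")
        if self.gene_set_size > self.n_promoters:
            raise ValueError("gene set larger than the universe")
        if not 0 <= self.overlap_bp <= self.motif_width:
            raise ValueError("overlap_bp must be in [0, motif_width]")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantingPlan":
        data = json.loads(Path(path).read_text())
        if "background" in data:
            data["background"] = tuple(data["background"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["background"] = list(d["background"])
        return d


def _gene_id(i: int) -> str:
    return f"g{i:06d}"


def generate_background_promoters(
    count: int,
    length: int,
    composition: Background | None = None,
    seed: int = 0,
) -> PromoterUniverse:
    """i.i.d. promoter sequences under a 0-order composition."""
    if count < 1 or length < 1:
        raise ValueError("count and length must be >= 1")
    composition = composition or Background.uniform()
    rng = np.random.default_rng(seed)
    bases = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    draws = rng.choice(bases, size=(count, length), p=composition.freq)
    return PromoterUniverse(
        Promoter(_gene_id(i), draws[i].tobytes().decode("ascii"))
        for i in range(count)
    )


def _sample_instance(motif: Motif, rng: np.random.Generator,
                     consensus_only: bool) -> str:
    if consensus_only:
        return motif.consensus()
    cols = [rng.choice(4, p=row) for row in motif.matrix]
    return "".join(ALPHABET[c] for c in cols)


def _pick_strand(policy: str, rng: np.random.Generator) -> str:
    if policy == "both":
        return "+" if rng.random() < 0.5 else "-"
    return policy


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def random_motif(
    motif_id: str,
    width: int,
    rng: np.random.Generator,
    dominant_freq: float = 0.92,
) -> Motif:
    """A random motif with one dominant base per column.

    Each column puts ``dominant_freq`` on a uniformly chosen base and
    splits the remainder evenly: informative enough that sampled
    instances are recoverable, weak enough that mismatched instances
    drown in background.
    """
    mat = np.full((width, 4), (1.0 - dominant_freq) / 3.0)
    mat[np.arange(width), rng.integers(0, 4, size=width)] = dominant_freq
    return Motif(motif_id, mat)


def make_motif_library(plan: PlantingPlan, rng: np.random.Generator) -> list[Motif]:
    return [
        random_motif(f"M{i:03d}", plan.motif_width, rng, plan.dominant_freq)
        for i in range(plan.n_motifs)
    ]


def plant_motif_instances(
    universe: PromoterUniverse,
    motifs: Sequence[Motif],
    plan: PlantingPlan,
    rng: np.random.Generator | None = None,
) -> tuple[PromoterUniverse, list[dict]]:
    """Write sampled motif instances into a copy of the universe.

    The first ``plan.planted_motifs`` motifs are planted together in
    ``plan.planted_promoters`` promoters chosen at random.  Instances are
    placed at non-overlapping random positions, except in forced-overlap
    mode (``overlap_bp > 0``) where consecutive motif instances of a pair
    are placed with exactly that genomic intersection.  The returned
    truth table records every planted interval.
    """
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    planted = list(motifs[: plan.planted_motifs])
    ids = universe.gene_ids()
    chosen = sorted(rng.choice(len(ids), size=plan.planted_promoters, replace=False))
    truth: list[dict] = []
    new_promoters: dict[str, Promoter] = {g: universe[g] for g in ids}

    for row in chosen:
        gene_id = ids[row]
        seq = bytearray(universe[gene_id].sequence.encode("ascii"))
        occupied: list[tuple[int, int]] = []

        def place(motif: Motif, start: int, strand: str) -> None:
            inst = _sample_instance(motif, rng, plan.consensus_only)
            if strand == "-":
                inst = _revcomp(inst)
            seq[start : start + motif.width] = inst.encode("ascii")
            occupied.append((start, start + motif.width))
            truth.append(
                {
                    "gene_id": gene_id,
                    "motif_id": motif.motif_id,
                    "start": int(start),
                    "end": int(start + motif.width),
                    "strand": strand,
                }
            )

        def free_position(width: int) -> int:
            limit = len(seq) - width
            if limit < 0:
                raise ValueError(
                    f"promoter {gene_id!r} too short for a width-{width} instance"
                )
            for _ in range(200):
                pos = int(rng.integers(0, limit + 1))
                if all(pos >= e or pos + width <= s for s, e in occupied):
                    return pos
            raise ValueError(
                f"could not place a width-{width} instance in promoter "
                f"{gene_id!r} without overlap"
            )

        for _ in range(plan.instances_per_promoter):
            if plan.overlap_bp > 0 and len(planted) >= 2:
                # place pairs (A with B, then any further motifs singly)
                a, b = planted[0], planted[1]
                span = a.width + b.width - plan.overlap_bp
                limit = len(seq) - span
                if limit < 0:
                    raise ValueError(
                        f"promoter {gene_id!r} too short for a forced overlap"
                    )
                for _ in range(200):
                    pos = int(rng.integers(0, limit + 1))
                    if all(pos >= e or pos + span <= s for s, e in occupied):
                        break
                else:
                    raise ValueError(
                        f"could not place the forced-overlap pair in promoter "
                        f"{gene_id!r}"
                    )
                place(a, pos, _pick_strand(plan.strand_policy, rng))
                place(b, pos + a.width - plan.overlap_bp,
                      _pick_strand(plan.strand_policy, rng))
                for extra in planted[2:]:
                    place(extra, free_position(extra.width),
                          _pick_strand(plan.strand_policy, rng))
            else:
                for motif in planted:
                    place(motif, free_position(motif.width),
                          _pick_strand(plan.strand_policy, rng))

        new_promoters[gene_id] = Promoter(gene_id, seq.decode("ascii"))

    return PromoterUniverse(new_promoters.values()), truth


def build_gene_set(
    universe: PromoterUniverse,
    planted_genes: Sequence[str],
    size: int,
    positive_fraction: float,
    rng: np.random.Generator,
    name: str = "synthetic_set",
) -> tuple[list[str], list[str]]:
    """A gene set mixing pair-positive and background genes.

    Returns (ordered gene ids, the pair-positive subset).  Sampling is
    without replacement; the order is a random permutation (the set is
    treated as ranked for equalization purposes).
    """
    n_pos = int(round(size * positive_fraction))
    n_pos = min(n_pos, len(planted_genes))
    planted_set = set(planted_genes)
    background_pool = [g for g in universe.gene_ids() if g not in planted_set]
    if size - n_pos > len(background_pool):
        raise ValueError("not enough background genes for the requested set size")
    positives = [planted_genes[i] for i in
                 sorted(rng.choice(len(planted_genes), size=n_pos, replace=False))]
    negatives = [background_pool[i] for i in
                 sorted(rng.choice(len(background_pool), size=size - n_pos,
                                   replace=False))]
    combined = positives + negatives
    order = rng.permutation(len(combined))
    return [combined[i] for i in order], positives


def make_benchmark_scenario(
    plan: PlantingPlan, out_dir: str | Path
) -> dict[str, Path]:
    """Materialize a plan as an on-disk fixture bundle.

    Writes ``motifs.meme``, ``promoters.fa``, ``gene_set.txt`` and
    ``truth.json`` into ``out_dir``; the truth file names the planted
    pair, every planted interval, and the pair-positive members of the
    gene set.  Byte-identical for a fixed plan (including its seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(plan.seed)
    motifs = make_motif_library(plan, rng)
    universe = generate_background_promoters(
        plan.n_promoters,
        plan.promoter_length,
        Background(np.array(plan.background)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    universe, truth = plant_motif_instances(universe, motifs, plan, rng)
    planted_genes = sorted({t["gene_id"] for t in truth})
    gene_ids, positives = build_gene_set(
        universe,
        planted_genes,
        plan.gene_set_size,
        plan.pair_positive_fraction,
        rng,
    )

    paths = {
        "motifs": out_dir / "motifs.meme",
        "promoters": out_dir / "promoters.fa",
        "gene_set": out_dir / "gene_set.txt",
        "truth": out_dir / "truth.json",
    }
    write_meme_file(motifs, paths["motifs"],
                    background=Background(np.array(plan.background)))
    universe.write_fasta(paths["promoters"])
    paths["gene_set"].write_text("".join(f"{g}\n" for g in gene_ids))
    truth_doc = {
        "plan": plan.to_dict(),
        "planted_pair": [m.motif_id for m in motifs[: plan.planted_motifs]],
        "planted_genes": planted_genes,
        "gene_set_positives": sorted(positives),
        "planted_instances": truth,
    }
    paths["truth"].write_text(json.dumps(truth_doc, sort_keys=True, indent=1) + "\n")
    return paths
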