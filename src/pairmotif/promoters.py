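"""Promoter extraction and the promoter universe.

A promoter is the fixed-length window upstream of a gene's transcription
start site (default 1000 bp), oriented 5'->3' toward the TSS: minus-strand
genes are reverse-complemented.  The universe holds one promoter per
nuclear gene; genes on organellar sequences are excluded.  Windows are
truncated at chromosome boundaries and are NOT trimmed at neighboring
genes.  Internally coordinates are 0-based half-open; GFF3's 1-based
closed convention is converted at the boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# encoding used by the scanner: A=0 C=1 G=2 T=3, anything else = 4
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0..T=3, N/other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


@dataclass(frozen=True)
class Promoter:
    """An upstream window tied to a gene, oriented toward the TSS."""

    gene_id: str
    sequence: str
    source_interval: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if re.search(r"[^ACGTN]", seq):
            bad = re.search(r"[^ACGTN]", seq).group()  # type: ignore[union-attr]
            raise ValueError(
                f"promoter {self.gene_id!r}: invalid base {bad!r}"
            )
        object.__setattr__(self, "sequence", seq)
        if self.source_interval is not None:
            chrom, start, end, strand = self.source_interval
            if end - start != len(seq):
                raise ValueError(
                    f"promoter {self.gene_id!r}: interval length "
                    f"{end - start} != sequence length {len(seq)}"
                )
            if strand not in "+-":
                raise ValueError(f"promoter {self.gene_id!r}: bad strand {strand!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def encoded(self) -> np.ndarray:
        return encode_sequence(self.sequence)


class PromoterUniverse:
    """Mapping of gene_id -> Promoter with deterministic iteration order."""

    def __init__(self, promoters: Iterable[Promoter]):
        self._promoters: dict[str, Promoter] = {}
        for p in promoters:
            if p.gene_id in self._promoters:
                raise ValueError(f"duplicate gene id {p.gene_id!r}")
            self._promoters[p.gene_id] = p
        self._encoded_cache: tuple[np.ndarray, np.ndarray, list[str]] | None = None

    @property
    def promoters(self) -> dict[str, Promoter]:
        return self._promoters

    @property
    def size(self) -> int:
        return len(self._promoters)

    def __len__(self) -> int:
        return len(self._promoters)

    def __iter__(self) -> Iterator[Promoter]:
        return iter(self._promoters.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._promoters

    def __getitem__(self, gene_id: str) -> Promoter:
        return self._promoters[gene_id]

    def gene_ids(self) -> list[str]:
        return list(self._promoters)

    def max_length(self) -> int:
        return max((p.length for p in self), default=0)

    def encoded_matrix(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """All promoters as one (n_genes, max_length) uint8 matrix.

        Shorter promoters are right-padded with code 4 (treated like N by
        the scanner); the true lengths are returned alongside.  Cached.
        """
        if self._encoded_cache is None:
            ids = self.gene_ids()
            lengths = np.array([self._promoters[g].length for g in ids], dtype=int)
            width = int(lengths.max(initial=0))
            mat = np.full((len(ids), width), 4, dtype=np.uint8)
            for row, gid in enumerate(ids):
                enc = self._promoters[gid].encoded()
                mat[row, : enc.size] = enc
            self._encoded_cache = (mat, lengths, ids)
        return self._encoded_cache

    def base_composition(self) -> np.ndarray:
        counts = np.zeros(4, dtype=float)
        for p in self:
            enc = p.encoded()
            counts += np.bincount(enc[enc < 4], minlength=4)
        if counts.sum() == 0:
            raise ValueError("universe contains no A/C/G/T bases")
        return counts / counts.sum()

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(p.sequence), id=p.gene_id, description="")
            for p in self
        ]
        SeqIO.write(records, str(path), "fasta")


DEFAULT_EXCLUDED_PATTERN = re.compile(
    r"^(chr)?(m|mt|c|pt|mito\w*|mitochondri\w*|chloroplast\w*|plastid\w*)$",
    re.IGNORECASE,
)


def _is_excluded(seqid: str, excluded_seqids: Sequence[str] | None) -> bool:
    if excluded_seqids is not None:
        return seqid in set(excluded_seqids)
    return bool(DEFAULT_EXCLUDED_PATTERN.match(seqid))


def extract_promoters(
    genome: str | Path,
    annotation: str | Path,
    promoter_length: int = 1000,
    excluded_seqids: Sequence[str] | None = None,
    feature_types: Sequence[str] = ("gene", "transposable_element_gene"),
) -> PromoterUniverse:
    """Extract upstream promoter windows from genome FASTA + GFF3.

    The TSS is the 5' end of each gene-level feature: GFF start for plus
    strand, GFF end for minus strand.  Transposable-element genes are
    included; features on excluded seqids (organellar chromosomes by
    default) are omitted.  Windows are truncated at chromosome ends; a
    feature without a strand is skipped with a warning; a seqid present in
    the annotation but missing from the FASTA raises.
    """
    import gffutils
    from pyfaidx import Fasta

    if promoter_length < 1:
        raise ValueError("promoter_length must be >= 1")
    fasta = Fasta(str(genome), sequence_always_upper=True)
    db = gffutils.create_db(
        str(annotation),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    promoters: list[Promoter] = []
    seen: set[str] = set()
    for ftype in feature_types:
        for feature in db.features_of_type(ftype, order_by=("seqid", "start")):
            if _is_excluded(feature.seqid, excluded_seqids):
                continue
            gene_id = feature.attributes.get("ID", [feature.id])[0]
            if gene_id in seen:
                logger.warning("duplicate gene feature %r; keeping first", gene_id)
                continue
            if feature.strand not in ("+", "-"):
                logger.warning("gene %r has no strand; skipped", gene_id)
                continue
            if feature.seqid not in fasta:
                raise KeyError(
                    f"seqid {feature.seqid!r} from annotation not in genome FASTA"
                )
            chrom_len = len(fasta[feature.seqid])
            if feature.strand == "+":
                tss0 = feature.start - 1  # 0-based position of the TSS base
                start = max(0, tss0 - promoter_length)
                end = tss0
                seq = fasta[feature.seqid][start:end].seq
            else:
                tss0 = feature.end  # window begins just past the TSS base
                start = tss0
                end = min(chrom_len, tss0 + promoter_length)
                seq = reverse_complement(fasta[feature.seqid][start:end].seq)
            if end <= start:
                logger.warning("gene %r has an empty promoter window; skipped",
                               gene_id)
                continue
            seen.add(gene_id)
            promoters.append(
                Promoter(
                    gene_id,
                    seq,
                    source_interval=(feature.seqid, start, end, feature.strand),
                )
            )
    return PromoterUniverse(promoters)


def load_promoter_fasta(
    path: str | Path, promoter_length: int = 1000
) -> PromoterUniverse:
    """Load a pre-extracted promoter FASTA (record IDs are gene IDs).

    Sequences are uppercased; duplicate IDs or records longer than
    ``promoter_length`` are errors (the latter cannot have been produced
    by this tool's windowing convention).
    """
    promoters = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if len(seq) > promoter_length:
            raise ValueError(
                f"record {record.id!r} is {len(seq)} bp, longer than the "
                f"configured promoter length {promoter_length}"
            )
        promoters.append(Promoter(record.id, seq))
    return PromoterUniverse(promoters)
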