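"""Sequence I/O and translation-start-anchored coordinates.

Everything downstream of this module (promoter windows, DNase-I footprints,
operator sites) is positioned relative to a gene's translation start using
signed *anchored* coordinates: −1 is the base immediately 5′ of the first
base of the start codon, +1 is the first base of the start codon itself, and
position 0 does not exist.  For genes on the − strand "upstream" means higher
genomic coordinate; all anchored operations are defined in the gene's reading
orientation and the conversion helpers below take care of the strand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

VALID_ALPHABET = set("ACGTN")
START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}

__all__ = [
    "ClusterRecord",
    "CdsFeature",
    "AnchoredInterval",
    "ClusterValidationError",
    "UnsupportedFeatureError",
    "read_cluster",
    "write_fasta",
    "to_anchored",
    "from_anchored",
    "anchored_ordinal",
    "ordinal_to_anchored",
    "find_tta_codons",
    "insilico_pcr",
    "extract_upstream",
    "revcomp",
]


class ClusterValidationError(ValueError):
    """A sequence record or CDS feature violates an invariant."""


class UnsupportedFeatureError(ValueError):
    """Input uses a feature outside this implementation's scope."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature on a cluster, 1-based inclusive coordinates."""

    gene: str
    start: int
    end: int
    strand: str  # "+" or "-"
    start_codon: str = "ATG"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ClusterValidationError(f"{self.gene}: strand must be + or -")
        if self.start < 1 or self.end < self.start:
            raise ClusterValidationError(f"{self.gene}: bad coordinates {self.start}..{self.end}")
        if (self.end - self.start + 1) % 3 != 0:
            raise ClusterValidationError(
                f"{self.gene}: CDS length {self.end - self.start + 1} not divisible by 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def coding_sequence(self, record: "ClusterRecord") -> str:
        s = record.sequence[self.start - 1 : self.end]
        return revcomp(s) if self.strand == "-" else s


@dataclass
class ClusterRecord:
    id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)
    source_format: str = "fasta"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ClusterValidationError("empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ClusterValidationError(f"invalid characters in sequence: {sorted(bad)}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ClusterValidationError(f"{f.gene}: feature end {f.end} beyond record length")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, gene: str) -> CdsFeature:
        for f in self.features:
            if f.gene == gene:
                return f
        raise KeyError(gene)

    def validate_start_codons(self) -> None:
        """Check each feature's annotated start codon against the sequence."""
        for f in self.features:
            if f.strand == "+":
                obs = self.sequence[f.start - 1 : f.start + 2]
            else:
                obs = revcomp(self.sequence[f.end - 3 : f.end])
            if obs != f.start_codon:
                raise ClusterValidationError(
                    f"{f.gene}: annotated start codon {f.start_codon} but sequence has {obs}"
                )


def _read_feature_tsv(path: Path) -> list[CdsFeature]:
    feats = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            try:
                feats.append(
                    CdsFeature(
                        gene=row["gene"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        strand=row["strand"],
                        start_codon=row.get("start_codon", "ATG") or "ATG",
                    )
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, ClusterValidationError):
                    raise
                raise ClusterValidationError(f"{path}: malformed feature row at line {i}: {exc}")
    return feats


def read_cluster(path: str | Path, fmt: str = "genbank", feature_tsv: str | Path | None = None) -> ClusterRecord:
    """Read a cluster as GenBank (features embedded) or FASTA (+ feature TSV).

    Lower-case input is upper-cased.  CDS features whose span is not a
    multiple of 3 raise :class:`ClusterValidationError` naming the gene.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "genbank":
        rec = SeqIO.read(str(path), "genbank")
        feats = []
        for sf in rec.features:
            if sf.type != "CDS":
                continue
            gene = sf.qualifiers.get("gene", sf.qualifiers.get("locus_tag", ["?"]))[0]
            start = int(sf.location.start) + 1  # Biopython is 0-based half-open
            end = int(sf.location.end)
            strand = "-" if sf.location.strand == -1 else "+"
            seq = str(rec.seq[start - 1 : end]).upper()
            codon = revcomp(seq[-3:]) if strand == "-" else seq[:3]
            feats.append(CdsFeature(gene, start, end, strand, codon))
        return ClusterRecord(rec.id, str(rec.seq), feats, source_format="genbank")
    if fmt == "fasta":
        rec = SeqIO.read(str(path), "fasta")
        feats = _read_feature_tsv(Path(feature_tsv)) if feature_tsv else []
        return ClusterRecord(rec.id, str(rec.seq), feats, source_format="fasta")
    raise UnsupportedFeatureError(f"unknown format {fmt!r}")


def write_fasta(record: ClusterRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.id}\n")
        for i in range(0, len(record.sequence), 70):
            fh.write(record.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Anchored coordinates


def anchored_ordinal(pos: int) -> int:
    """Map a signed anchored position (no 0) onto the integers.

    −1 → −1, +1 → 0, so consecutive anchored bases are consecutive ordinals
    and interval arithmetic never trips over the missing zero.
    """
    if pos == 0:
        raise ValueError("anchored position 0 does not exist")
    return pos if pos < 0 else pos - 1


def ordinal_to_anchored(o: int) -> int:
    return o if o < 0 else o + 1


def to_anchored(genomic_pos: int, cds: CdsFeature) -> int:
    """Signed offset of a genomic position relative to a CDS translation start.

    −1 is the base immediately 5′ of the start codon; +1 is the first base of
    the start codon.  Strand-aware: for − strand genes upstream is the higher
    genomic coordinate.
    """
    if cds.strand == "+":
        d = genomic_pos - cds.start
    else:
        d = cds.end - genomic_pos
    return d + 1 if d >= 0 else d


def from_anchored(offset: int, cds: CdsFeature) -> int:
    """Inverse of :func:`to_anchored`; offset 0 is rejected."""
    if offset == 0:
        raise ValueError("anchored position 0 does not exist")
    d = offset - 1 if offset > 0 else offset
    return cds.start + d if cds.strand == "+" else cds.end - d


@dataclass(frozen=True)
class AnchoredInterval:
    """Inclusive interval in translation-start-anchored coordinates.

    ``strand_of_read`` records which physical strand the interval was read
    from ("top" = the gene's coding strand).  from/to are normalized so that
    ``from_pos`` ≤ ``to_pos`` in reading-direction order (e.g. −84..−55).
    """

    anchor_gene: str
    from_pos: int
    to_pos: int
    strand_of_read: str = "top"

    def __post_init__(self) -> None:
        if self.from_pos == 0 or self.to_pos == 0:
            raise ValueError("anchored position 0 does not exist")
        if self.strand_of_read not in {"top", "bottom"}:
            raise ValueError("strand_of_read must be 'top' or 'bottom'")
        lo, hi = sorted((self.from_pos, self.to_pos), key=anchored_ordinal)
        object.__setattr__(self, "from_pos", lo)
        object.__setattr__(self, "to_pos", hi)

    @property
    def ordinals(self) -> tuple[int, int]:
        return anchored_ordinal(self.from_pos), anchored_ordinal(self.to_pos)

    def positions(self) -> list[int]:
        lo, hi = self.ordinals
        return [ordinal_to_anchored(o) for o in range(lo, hi + 1)]

    def genomic(self, cds: CdsFeature) -> tuple[int, int]:
        a, b = from_anchored(self.from_pos, cds), from_anchored(self.to_pos, cds)
        return (a, b) if a <= b else (b, a)

    def sequence(self, record: ClusterRecord, cds: CdsFeature | None = None) -> str:
        """Bases of the interval read 5′→3′ on ``strand_of_read``.

        "top" means the gene's coding strand (reading toward the start codon);
        "bottom" is its reverse complement.
        """
        cds = cds if cds is not None else record.feature(self.anchor_gene)
        lo, hi = self.genomic(cds)
        s = record.sequence[lo - 1 : hi]
        if cds.strand == "-":
            s = revcomp(s)  # now in the gene's reading orientation (= top)
        return s if self.strand_of_read == "top" else revcomp(s)


# ---------------------------------------------------------------------------
# ORF utilities


def find_tta_codons(cds: CdsFeature, record: ClusterRecord) -> list[int]:
    """1-based codon indices of in-frame TTA (rare leucine) codons.

    TTA is a hallmark of secondary-metabolism regulatory genes in high-GC
    streptomycetes; out-of-frame TTA trinucleotides are ignored.
    """
    coding = cds.coding_sequence(record)
    return [i // 3 + 1 for i in range(0, len(coding) - 2, 3) if coding[i : i + 3] == "TTA"]


def _exact_matches(seq: str, primer: str) -> list[int]:
    """0-based start positions of exact matches; N never matches."""
    hits = []
    start = seq.find(primer)
    while start != -1:
        hits.append(start)
        start = seq.find(primer, start + 1)
    return hits


def insilico_pcr(record: ClusterRecord, fwd_primer: str, rev_primer: str) -> list[int]:
    """Exact-match in-silico PCR; returns sorted amplicon lengths.

    The forward primer is matched on the top strand and paired with every
    downstream reverse-complement occurrence of the reverse primer; the
    product length includes both primers.  Degenerate (IUPAC) primers are
    not supported.  Zero products is an empty list, not an error.
    """
    for name, p in (("forward", fwd_primer), ("reverse", rev_primer)):
        p = p.upper()
        if len(p) < 15:
            raise ValueError(f"{name} primer shorter than 15 nt")
        if set(p) - set("ACGT"):
            raise UnsupportedFeatureError(f"{name} primer contains degenerate/ambiguous bases")
    fwd, rev = fwd_primer.upper(), rev_primer.upper()
    rev_on_top = revcomp(rev)
    lengths = []
    for f in _exact_matches(record.sequence, fwd):
        for r in _exact_matches(record.sequence, rev_on_top):
            end = r + len(rev_on_top)  # exclusive
            if end > f + len(fwd) and r >= f:
                lengths.append(end - f)
    return sorted(lengths)


def extract_upstream(cds: CdsFeature, record: ClusterRecord, length: int) -> tuple[str, bool]:
    """Upstream sequence in anchored orientation (5′→3′ toward the start codon).

    Returns ``(seq, truncated)``; the last base of ``seq`` is anchored −1.
    ``truncated`` is True when the record edge cut the request short.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if cds.strand == "+":
        lo = max(1, cds.start - length)
        s = record.sequence[lo - 1 : cds.start - 1]
        return s, (cds.start - length) < 1
    hi = min(len(record.sequence), cds.end + length)
    s = revcomp(record.sequence[cds.end : hi])
    return s, (cds.end + length) > len(record.sequence)
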