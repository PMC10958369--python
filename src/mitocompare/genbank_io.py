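"""Reading and writing annotated mitogenomes.

This module owns every coordinate, strand, and genetic-code convention used
by the rest of the package:

* internal coordinates are 0-based half-open on the forward strand;
  GenBank's 1-based inclusive spans are converted at the I/O boundary;
* strands are named ``J`` (majority / forward) and ``N`` (minority /
  reverse), the standard labels for insect mitogenomes;
* a feature annotated across the origin of a circular molecule
  (``join(a..L,1..b)``) is a single :class:`GeneFeature` with
  ``wraps_origin=True``;
* the default genetic code is NCBI translation table 5 (invertebrate
  mitochondrial), overridable everywhere a code is taken.

Gene names are normalized to canonical lower-case symbols (``cox1``,
``nad4L``, ``trnS2``, ``d_loop`` ...) through an editable synonym table
shipped as package data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "GeneticCode",
    "GeneFeature",
    "MitoGenome",
    "GenBankParseError",
    "parse_genbank",
    "write_genbank",
    "feature_sequence",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "write_tsv",
]

#: The 13 mitochondrial protein-coding genes, in canonical alphabetical order.
PCG_NAMES: tuple[str, ...] = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

TRNA_NAMES: tuple[str, ...] = tuple(
    f"trn{x}" for x in (
        "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
        "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
    )
)

RRNA_NAMES: tuple[str, ...] = ("rrnS", "rrnL")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


class GenBankParseError(ValueError):
    """Raised when a GenBank record violates the parser's contract."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon genetic code.

    Wraps an NCBI translation table; the default everywhere in the package
    is table 5 (invertebrate mitochondrial: TGA=Trp, ATA=Met, AGA/AGG=Ser).
    """

    table_id: int
    codon_to_aa: Mapping[str, str]   # all 64 codons; stops map to '*'
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    @classmethod
    def from_table(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        if len(mapping) != 64:
            raise ValueError(f"translation table {table_id} is not complete")
        return cls(
            table_id=table_id,
            codon_to_aa=mapping,
            start_codons=frozenset(table.start_codons),
            stop_codons=frozenset(table.stop_codons),
        )

    def translate_codon(self, codon: str) -> str:
        """Amino acid for one codon; codons containing N yield 'X'."""
        if "N" in codon:
            return "X"
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def synonymous_families(self) -> dict[str, tuple[str, ...]]:
        """Map amino acid -> tuple of its sense codons (stops excluded)."""
        fams: dict[str, list[str]] = {}
        for codon, aa in sorted(self.codon_to_aa.items()):
            if aa == "*":
                continue
            fams.setdefault(aa, []).append(codon)
        return {aa: tuple(cods) for aa, cods in fams.items()}


DEFAULT_CODE = GeneticCode.from_table(5)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_KINDS = ("PCG", "tRNA", "rRNA", "control_region")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a mitogenome.

    ``start``/``end`` are 0-based half-open on the forward strand. A
    feature with ``wraps_origin=True`` runs from ``start`` through the
    origin to ``end`` (so ``start > end`` is expected there and only there).
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str  # 'J' or 'N'
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be 'J' or 'N', got {self.strand!r}")

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return (genome_length - self.start) + self.end
        return self.end - self.start


@dataclass
class MitoGenome:
    """An annotated (usually circular, ~16 kb) mitochondrial genome."""

    id: str
    sequence: str
    circular: bool
    features: list[GeneFeature] = field(default_factory=list)
    source_taxon: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise GenBankParseError(
                f"{self.id}: ambiguity codes other than N are not supported "
                f"(found {sorted(bad)})"
            )
        L = len(self.sequence)
        for feat in self.features:
            if not (0 <= feat.start < L) or not (0 <= feat.end <= L):
                raise GenBankParseError(
                    f"{self.id}: feature {feat.name} coordinates "
                    f"[{feat.start}, {feat.end}) outside [0, {L})"
                )
            if feat.wraps_origin and not self.circular:
                raise GenBankParseError(
                    f"{self.id}: feature {feat.name} wraps the origin of a "
                    "linear record"
                )
            if feat.kind == "PCG" and feat.length(L) < 3:
                raise GenBankParseError(
                    f"{self.id}: PCG {feat.name} shorter than one codon"
                )
        self.features.sort(key=lambda f: (f.start, f.end))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def pcgs(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "PCG"]

    def get(self, name: str) -> GeneFeature | None:
        for feat in self.features:
            if feat.name == name:
                return feat
        return None


# ---------------------------------------------------------------------------
# Gene-name normalization (data-driven)
# ---------------------------------------------------------------------------

def _load_synonyms() -> dict[str, str]:
    text = (
        resources.files("mitocompare").joinpath("data/gene_synonyms.tsv")
        .read_text()
    )
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, canonical = line.split("\t")
        table[alias.strip().lower()] = canonical.strip()
    return table


_SYNONYMS: dict[str, str] | None = None


def normalize_gene_name(raw: str) -> str | None:
    """Canonical symbol for ``raw``, or None if the alias is unknown."""
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    key = raw.strip().lower().replace(" ", "").replace("_", "-")
    return _SYNONYMS.get(key)


def _kind_for(name: str) -> str:
    if name in PCG_NAMES:
        return "PCG"
    if name.startswith("trn"):
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    if name == "d_loop":
        return "control_region"
    raise ValueError(f"cannot infer kind for {name!r}")


_FEATUREKEY_KIND = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control_region",
    "misc_feature": "control_region",
}


# ---------------------------------------------------------------------------
# GenBank parsing
# ---------------------------------------------------------------------------

def _feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        vals = feat.qualifiers.get(key)
        if vals:
            return str(vals[0])
    return ""


def _convert_location(
    feat: SeqFeature, length: int, circular: bool, rec_id: str
) -> tuple[int, int, str, bool]:
    """GenBank location -> (start, end, strand, wraps_origin)."""
    loc = feat.location
    strand = "N" if loc.strand == -1 else "J"
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # An origin-spanning join has one part ending at L and one starting at 0.
        if (
            len(parts) == 2
            and int(parts[0].start) == 0
            and int(parts[1].end) == length
        ):
            if not circular:
                raise GenBankParseError(
                    f"{rec_id}: origin-spanning feature on a linear record"
                )
            return int(parts[1].start), int(parts[0].end), strand, True
        # Other joins (e.g. trans-splicing) do not occur in mitogenomes.
        start = int(parts[0].start)
        end = int(parts[-1].end)
        return start, end, strand, False
    return int(loc.start), int(loc.end), strand, False


def _disambiguate_duplicate_trnas(features: list[GeneFeature]) -> list[GeneFeature]:
    """Leu/Ser tRNAs annotated without an isotype number get one by order."""
    out: list[GeneFeature] = []
    seen: dict[str, int] = {}
    for feat in features:
        name = feat.name
        if name in ("trnL", "trnS"):
            idx = seen.get(name, 0) + 1
            seen[name] = idx
            name = f"{name}{min(idx, 2)}"
            feat = replace(feat, name=name)
        out.append(feat)
    return out


def parse_genbank(path: str | Path, *, code: GeneticCode = DEFAULT_CODE) -> list[MitoGenome]:
    """Parse a GenBank flat file into one :class:`MitoGenome` per record.

    Gene names are normalized through the synonym table; features with an
    unknown name are kept with a warning, their kind inferred from the
    feature key. Duplicate annotations of the same gene (a ``gene`` span
    plus its ``CDS``) collapse to a single feature.
    """
    path = Path(path)
    genomes: list[MitoGenome] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenBankParseError(f"{path}: {exc}") from exc
    if not records:
        raise GenBankParseError(f"{path}: no GenBank records found")
    for rec in records:
        try:
            seq = str(rec.seq).upper()
        except Bio_UndefinedSequenceError:  # pragma: no cover - biopython detail
            raise GenBankParseError(f"{path}: record {rec.id} has no ORIGIN sequence")
        if not seq or set(seq) == {"N"} and not rec.seq:
            raise GenBankParseError(f"{path}: record {rec.id} has no ORIGIN sequence")
        circular = rec.annotations.get("topology", "linear") == "circular"
        feats: list[GeneFeature] = []
        seen_spans: set[tuple[int, int, str, str]] = set()
        for feat in rec.features:
            kind_hint = _FEATUREKEY_KIND.get(feat.type)
            if feat.type not in ("gene", "CDS", "tRNA", "rRNA", "D-loop", "misc_feature"):
                continue
            raw = _feature_name(feat)
            if feat.type == "D-loop" and not raw:
                raw = "d-loop"
            name = normalize_gene_name(raw)
            if name is None:
                if feat.type == "gene":
                    continue
                if kind_hint is None:
                    continue
                warnings.warn(
                    f"{rec.id}: gene name {raw!r} not in synonym table; "
                    f"keeping with kind {kind_hint}",
                    stacklevel=2,
                )
                name = raw.strip().replace(" ", "_") or f"unnamed_{feat.type}"
                kind = kind_hint
            else:
                kind = _kind_for(name) if name not in ("trnL", "trnS") else "tRNA"
            if feat.type == "gene" and kind == "PCG":
                # the CDS carries the authoritative span
                continue
            if feat.type == "misc_feature" and kind != "control_region":
                continue
            start, end, strand, wraps = _convert_location(
                feat, len(seq), circular, rec.id
            )
            key = (start, end, strand, name)
            if key in seen_spans:
                continue
            seen_spans.add(key)
            feats.append(
                GeneFeature(
                    name=name, kind=kind, start=start, end=end,
                    strand=strand, wraps_origin=wraps,
                )
            )
        feats = _disambiguate_duplicate_trnas(feats)
        organism = rec.annotations.get("organism", "")
        genomes.append(
            MitoGenome(
                id=rec.name or rec.id,
                sequence=seq,
                circular=circular,
                features=feats,
                source_taxon=organism,
            )
        )
    return genomes


# Biopython raises this from inside Seq when ORIGIN is absent.
try:  # pragma: no cover - import guard
    from Bio.Seq import UndefinedSequenceError as Bio_UndefinedSequenceError
except ImportError:  # pragma: no cover
    class Bio_UndefinedSequenceError(Exception):
        pass


def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    """Write a MitoGenome back out as a GenBank flat file."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description=f"{genome.source_taxon} mitochondrion".strip(),
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.source_taxon,
        },
    )
    L = genome.length
    for feat in genome.features:
        strand = 1 if feat.strand == "J" else -1
        if feat.wraps_origin:
            loc = CompoundLocation(
                [
                    SimpleLocation(feat.start, L, strand),
                    SimpleLocation(0, feat.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(feat.start, feat.end, strand)
        ftype = {
            "PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
            "control_region": "D-loop",
        }[feat.kind]
        rec.features.append(
            SeqFeature(loc, type=ftype, qualifiers={"gene": [feat.name]})
        )
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def feature_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Coding-sense nucleotide sequence of one feature.

    Strand-J features are the forward slice; strand-N features are
    reverse-complemented. Origin-wrapping features concatenate
    ``[start, L) + [0, end)``. Trailing partial codons of PCGs are kept —
    downstream codon operations trim them.
    """
    if feature not in genome.features:
        raise ValueError(f"feature {feature.name} does not belong to {genome.id}")
    if feature.wraps_origin:
        raw = genome.sequence[feature.start:] + genome.sequence[: feature.end]
    else:
        raw = genome.sequence[feature.start: feature.end]
    if feature.strand == "N":
        return reverse_complement(raw)
    return raw


def gene_sequences(
    genome: MitoGenome, genes: Sequence[str] = PCG_NAMES
) -> dict[str, str]:
    """Coding-sense sequences for the requested genes (missing ones omitted)."""
    out: dict[str, str] = {}
    for name in genes:
        feat = genome.get(name)
        if feat is not None:
            out[name] = feature_sequence(genome, feat)
    return out


# ---------------------------------------------------------------------------
# FASTA / TSV plumbing
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path, *, width: int = 60) -> None:
    """Write named sequences as 60-column-wrapped FASTA."""
    names = list(seqs)
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence names")
    if not seqs:
        warnings.warn(f"writing empty FASTA file {path}", stacklevel=2)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_tsv(table, path: str | Path) -> None:
    """Write a pandas DataFrame as TSV with a header row."""
    table.to_csv(path, sep="\t", index=False)


def iter_genomes(paths: Iterable[str | Path]) -> list[MitoGenome]:
    """Parse several GenBank files into a flat genome list."""
    genomes: list[MitoGenome] = []
    for p in paths:
        genomes.extend(parse_genbank(p))
    return genomes
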