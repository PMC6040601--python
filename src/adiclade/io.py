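"""Readers and writers for the external formats the toolkit consumes.

Formats: FASTA (plain and aligned, gap character "-"), EMBL flat files
(ID/DE/OS/FT CDS/SQ), newick with bootstrap support serialized as internal
node labels, and TSV reports whose header lines start with "#". FASTA and
EMBL parsing is delegated to Biopython; newick handling to dendropy.

FASTA headers round-trip the record metadata through bracketed key=value
tokens, e.g. ``>rec1 [species=Homo sapiens] [cluster=ADIF]``.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

from .records import CodingRecord, GeneFamilySet, VALID_NUCLEOTIDES

logger = logging.getLogger(__name__)

_META_TOKEN = re.compile(r"\[(\w+)=([^\]]*)\]")

#: Controlled vocabulary of major gene-cluster labels for the deposited
#: eutherian adiponectin data set (18 orthologue groups). Documented, not
#: enforced: cluster labels are free-form strings.
ADI_CLUSTERS: tuple[str, ...] = tuple(f"ADI{c}" for c in "ABCDEFGHIJKLMNOPQR")

_CLUSTER_RE = re.compile(r"\b(ADI[A-R])\d*\b")


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA


def _parse_header_meta(description: str) -> dict[str, str]:
    return {k: v for k, v in _META_TOKEN.findall(description)}


def read_fasta(path: str | Path, frame_checked: bool = False) -> list[CodingRecord]:
    """Read coding records from a (possibly aligned) FASTA file.

    Metadata is taken from ``[species=...]`` / ``[cluster=...]`` /
    ``[exons=...]`` header tokens when present. With ``frame_checked`` the
    full :class:`CodingRecord` invariants are enforced (in-frame length, no
    internal stop, alphabet {A,C,G,T,N}); otherwise only the alphabet is
    checked, with gaps tolerated for aligned input.
    """
    path = Path(path)
    records: list[CodingRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        if not seqrec.id:
            raise ParseError(f"{path}: FASTA entry with empty header id")
        meta = _parse_header_meta(seqrec.description)
        seq = str(seqrec.seq).upper().replace(".", "-")
        bad = set(seq) - VALID_NUCLEOTIDES - {"-"}
        if bad:
            raise ParseError(
                f"{path}: record {seqrec.id!r} contains unsupported letters "
                f"{sorted(bad)} (ambiguity codes other than N are rejected)"
            )
        exons = None
        if "exons" in meta and meta["exons"]:
            exons = [int(x) for x in meta["exons"].split(",")]
        rec = CodingRecord(
            record_id=seqrec.id,
            species=meta.get("species", "unknown"),
            cluster=meta.get("cluster", ""),
            cds=seq,
            exon_lengths=exons,
            is_reference=meta.get("reference", "") in ("1", "true", "yes"),
        )
        if frame_checked:
            if "-" in rec.cds:
                raise ParseError(
                    f"{path}: record {seqrec.id!r} contains gaps; frame-checked "
                    "input must be ungapped CDS"
                )
            rec.validate()
        records.append(rec)
    return records


def write_fasta(
    records: Iterable[CodingRecord], path: str | Path, width: int = 70
) -> None:
    """Write records as FASTA, embedding metadata in header tokens."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            tokens = []
            if rec.species and rec.species != "unknown":
                tokens.append(f"[species={rec.species}]")
            if rec.cluster:
                tokens.append(f"[cluster={rec.cluster}]")
            if rec.exon_lengths:
                tokens.append(f"[exons={','.join(str(e) for e in rec.exon_lengths)}]")
            if rec.is_reference:
                tokens.append("[reference=1]")
            header = rec.record_id + (" " + " ".join(tokens) if tokens else "")
            fh.write(f">{header}\n")
            for i in range(0, len(rec.cds), width):
                fh.write(rec.cds[i : i + width] + "\n")


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA (protein or nucleotide) as (id, row) pairs.

    Rows are uppercased, "." gaps normalized to "-", and required to share
    one length.
    """
    path = Path(path)
    rows = [
        (rec.id, str(rec.seq).upper().replace(".", "-"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if rows:
        lengths = {len(r) for _, r in rows}
        if len(lengths) > 1:
            raise ParseError(f"{path}: alignment rows differ in length: {sorted(lengths)}")
    return rows


def write_aligned_fasta(
    rows: Sequence[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    with open(Path(path), "w") as fh:
        for rid, row in rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# EMBL flat files


def read_embl_cds(path: str | Path, cluster_pattern: re.Pattern = _CLUSTER_RE) -> list[CodingRecord]:
    """Read coding records from an EMBL flat file.

    One :class:`CodingRecord` per entry. Species comes from the OS line
    (``"unknown"``, with a logged warning, when absent). The major
    gene-cluster label is recovered by regex over the gene qualifiers of
    CDS features and the DE description line — the deposited third-party
    data records carry labels like ``ADIF2`` whose cluster is ``ADIF``.
    When the entry has a CDS feature on the forward strand, its extracted
    sequence is used; otherwise the whole entry sequence is taken as CDS.
    """
    path = Path(path)
    try:
        seqrecs = list(SeqIO.parse(str(path), "embl"))
    except ValueError as exc:
        raise ParseError(f"{path}: EMBL parse failure: {exc}") from exc
    if not seqrecs:
        raise ParseError(f"{path}: no EMBL entries found (missing ID/SQ blocks?)")
    records: list[CodingRecord] = []
    for seqrec in seqrecs:
        if len(seqrec.seq) == 0:
            raise ParseError(f"{path}: entry {seqrec.id!r} has no SQ sequence block")
        species = seqrec.annotations.get("organism", "") or "unknown"
        if species == "unknown":
            logger.warning("EMBL entry %s lacks an OS line; species set to 'unknown'",
                           seqrec.id)
        cds = str(seqrec.seq).upper()
        gene_names: list[str] = []
        for feat in seqrec.features:
            if feat.type == "CDS":
                gene_names.extend(feat.qualifiers.get("gene", []))
                try:
                    cds = str(feat.extract(seqrec.seq)).upper()
                except Exception:  # unresolved location: keep whole sequence
                    pass
        haystack = " ".join(gene_names + [seqrec.description or ""])
        m = cluster_pattern.search(haystack)
        cluster = m.group(1) if m else ""
        records.append(
            CodingRecord(
                record_id=seqrec.id, species=species, cluster=cluster, cds=cds
            )
        )
    return records


def read_embl_dir(directory: str | Path) -> GeneFamilySet:
    """Read every ``*.embl``/``*.dat``/``*.txt`` EMBL file in a directory."""
    directory = Path(directory)
    records: list[CodingRecord] = []
    paths = sorted(
        p for ext in ("*.embl", "*.dat", "*.txt") for p in directory.glob(ext)
    )
    for p in paths:
        records.extend(read_embl_cds(p))
    return GeneFamilySet(records=records)


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: "dendropy.Tree | object", path: str | Path) -> None:
    """Write a tree as newick with supports as internal node labels.

    Accepts a dendropy tree or any object with ``to_dendropy()`` (the
    phylogeny module's :class:`PhyloTree`). Branch lengths are written to 6
    decimals so round-trips preserve them exactly at that precision.
    """
    dtree = tree if isinstance(tree, dendropy.Tree) else tree.to_dendropy()
    for node in dtree.internal_nodes():
        if node.label is None and getattr(node, "support", None) is not None:
            node.label = str(node.support)
    s = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    Path(path).write_text(s)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a newick tree; internal node labels are bootstrap supports."""
    tree = dendropy.Tree.get(
        path=str(Path(path)), schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


# ---------------------------------------------------------------------------
# TSV reports


def write_tsv(
    path: str | Path,
    header_lines: Sequence[str],
    columns: Sequence[str],
    rows: Iterable[Sequence],
) -> None:
    """Write a TSV report with '#'-prefixed header lines.

    All coordinates in reports are 1-based inclusive; callers state this in
    their header lines.
    """
    with open(Path(path), "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
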