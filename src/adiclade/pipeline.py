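"""End-to-end orchestration of the comparative-genomics protocol.

Stage order: reliability testing of candidate coding sequences →
codon-aware alignment threading → pairwise identity statistics →
minimum-evolution tree with bootstrap → RSCU and site classification →
protein landmarks. A one-command synthetic demo generates a family with
the built-in simulator and runs every stage against it; the reproduction
harness recomputes the published statistics from user-supplied copies of
the deposited data set.

Outputs are plain TSV/newick/key=value text; reruns with the same config
and seed are byte-identical, and the run manifest records parameters and
the SHA-256 checksum of every stage output.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .codon_align import thread_nucleotides, translate
from .codon_evolution import classify_sites, codon_usage, rscu, site_report
from .identity import (
    cluster_summaries,
    pattern_label,
    summarize_alignment,
)
from .io import (
    read_aligned_fasta,
    read_embl_dir,
    read_fasta,
    write_aligned_fasta,
    write_fasta,
    write_newick,
    write_tsv,
)
from .landmarks import annotate
from .phylogeny import SaturationError, bootstrap, cluster_groups, distances, me_tree
from .records import SYNONYMOUS_FAMILIES, GeneFamilySet
from .reliability import batch_reliability
from .simulate import SimulationConfig, simulate_family, simulate_reads, write_reads_fastq
from . import reference_data as ref

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (flat key=value file round-trip)."""

    # inputs ("" = not supplied)
    cds_path: str = ""
    reads_path: str = ""
    protein_alignment_path: str = ""
    # stage toggles
    simulate: bool = False
    stage_reliability: bool = True
    stage_identity: bool = True
    stage_tree: bool = True
    stage_siteclass: bool = True
    stage_landmarks: bool = True
    # parameters
    min_support: int = 1
    min_seed: int = 16
    max_mismatch_frac: float = 0.05
    gap_mode: str = "pairwise_deletion"
    model: str = "TN93_pooled"
    search: str = "nj_plus_nni"
    bootstrap_replicates: int = 100
    r_threshold: float = 0.7
    repeat_max_mismatch: int = 2
    read_depth: float = 10.0
    read_length: int = 50
    # bookkeeping
    out_dir: str = "adiclade_out"
    seed: int = 0

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k}={v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: type(getattr(cls(), f.name)) for f in cls.__dataclass_fields__.values()}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            k = k.strip()
            if k not in types:
                raise ValueError(f"unknown config key {k!r}")
            t = types[k]
            kwargs[k] = (v.strip().lower() in ("1", "true", "yes")) if t is bool else t(v.strip())
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the manifest.

    Raises a configuration error before any work when an enabled stage
    lacks its required input. The manifest (also written to
    ``manifest.txt``) records the package version, every parameter, and
    per-stage output files with SHA-256 checksums.
    """
    out = Path(config.out_dir)
    # --- validate inputs up front
    if not config.simulate:
        if not config.cds_path:
            raise ValueError("cds_path is required unless simulate=true")
        if config.stage_reliability and not config.reads_path:
            raise ValueError("stage_reliability needs reads_path (or simulate=true)")
        needs_aln = config.stage_identity or config.stage_tree or \
            config.stage_siteclass or config.stage_landmarks
        if needs_aln and not config.protein_alignment_path:
            raise ValueError("downstream stages need protein_alignment_path "
                             "(or simulate=true)")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"adiclade_version": __version__}
    manifest.update({f"param.{k}": v for k, v in asdict(config).items()})
    outputs: list[Path] = []

    def emit(path: Path) -> Path:
        outputs.append(path)
        return path

    # --- inputs (simulated or loaded)
    truth = None
    reads_by_record = None
    if config.simulate:
        sim_cfg = SimulationConfig(seed=config.seed)
        family, truth = simulate_family(sim_cfg)
        write_fasta(family.records, emit(out / "cds.fasta"))
        (out / "true_tree.nwk").write_text(truth.true_tree + "\n")
        emit(out / "true_tree.nwk")
        write_tsv(
            emit(out / "truth_invariant_columns.tsv"),
            ["Simulation truth: invariant codon columns (1-based, root coordinates)"],
            ["codon_column"],
            [(c,) for c in sorted(truth.invariant_columns)],
        )
        reads_by_record = {}
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xEAD5)))
        for rec in family.records:
            reads_by_record[rec.record_id] = simulate_reads(
                rec, depth=config.read_depth, read_length=config.read_length,
                seed=int(rng.integers(2**31)),
            )
        write_reads_fastq(
            [r for reads in reads_by_record.values() for r in reads],
            emit(out / "reads.fastq"),
        )
        protein_aln = [
            (rid, row) for rid, row in truth.protein_alignment
        ]
    else:
        family = GeneFamilySet(records=read_fasta(config.cds_path, frame_checked=True))
        if config.stage_reliability:
            from .simulate import read_reads

            all_reads = read_reads(config.reads_path)
            reads_by_record = {r.record_id: [] for r in family.records}
            for rd in all_reads:
                rid = rd.read_id.rsplit("_r", 1)[0]
                reads_by_record.setdefault(rid, []).append(rd)
        protein_aln = (
            read_aligned_fasta(config.protein_alignment_path)
            if config.protein_alignment_path
            else None
        )

    # --- reliability
    if config.stage_reliability:
        summary = batch_reliability(
            family.records, reads_by_record, min_support=config.min_support,
            min_seed=config.min_seed, max_mismatch_frac=config.max_mismatch_frac,
        )
        rows = [
            (rid, rep.verdict, len(rep.uncovered),
             ";".join(f"{a}-{b}" for a, b in rep.uncovered_ranges()))
            for rid, rep in summary.reports.items()
        ]
        write_tsv(
            emit(out / "reliability.tsv"),
            ["Reliability verdicts (uncovered ranges are 1-based inclusive)",
             f"n_complete={summary.n_complete} n_putative={summary.n_putative}"],
            ["record_id", "verdict", "n_uncovered", "uncovered_ranges"],
            rows,
        )
        manifest["reliability.n_complete"] = summary.n_complete
        manifest["reliability.n_putative"] = summary.n_putative
        complete = set(summary.complete_ids)
        family = GeneFamilySet(records=[r for r in family.records if r.record_id in complete])
        if protein_aln is not None:
            protein_aln = [(rid, row) for rid, row in protein_aln if rid in complete]
    else:
        manifest["reliability.skipped"] = True

    # --- threading
    aln = None
    if protein_aln is not None and len(family) >= 1:
        aln = thread_nucleotides(protein_aln, family.records)
        write_aligned_fasta(
            list(zip(aln.record_ids, aln.nucleotide_rows)), emit(out / "codon_alignment.fasta")
        )

    cluster_of = {r.record_id: r.cluster for r in family.records}
    nuc_rows = list(zip(aln.record_ids, aln.nucleotide_rows)) if aln else None

    # --- identity
    if config.stage_identity and nuc_rows and len(nuc_rows) >= 2:
        ident = summarize_alignment(nuc_rows, gap_mode=config.gap_mode)
        write_tsv(
            emit(out / "identity_matrix.tsv"),
            ["Pairwise nucleotide identity matrix (proportions)"],
            ["id"] + ident.ids,
            [[rid] + [f"{v:.6f}" for v in row] for rid, row in zip(ident.ids, ident.matrix)],
        )
        per_cluster = cluster_summaries(nuc_rows, cluster_of, gap_mode=config.gap_mode)
        write_tsv(
            emit(out / "identity_summary.tsv"),
            ["Identity summaries: a_bar, a_bar_ad, a_max, a_min (3 decimals)"],
            ["scope", "n", "a_bar", "a_bar_ad", "a_max", "a_min", "pattern"],
            [["all", len(ident.ids), f"{ident.a_bar:.3f}", f"{ident.a_bar_ad:.3f}",
              f"{ident.a_max:.3f}", f"{ident.a_min:.3f}", pattern_label(ident)]]
            + [[label, len(s.ids), f"{s.a_bar:.3f}", f"{s.a_bar_ad:.3f}",
                f"{s.a_max:.3f}", f"{s.a_min:.3f}", pattern_label(s)]
               for label, s in per_cluster.items()],
        )
        manifest["identity.a_bar"] = round(ident.a_bar, 6)
    else:
        manifest["identity.skipped"] = True

    # --- tree
    if config.stage_tree and nuc_rows and len(nuc_rows) >= 3:
        tree = bootstrap(
            nuc_rows, model=config.model, replicates=config.bootstrap_replicates,
            seed=config.seed, search=config.search,
        )
        write_newick(tree, emit(out / "me_tree.nwk"))
        dm = distances(nuc_rows, model=config.model)
        write_tsv(
            emit(out / "distances.tsv"),
            [f"Pairwise distances, model={config.model}, pairwise deletion"],
            ["id"] + dm.ids,
            [[rid] + [f"{v:.6f}" for v in row] for rid, row in zip(dm.ids, dm.d)],
        )
        manifest["tree.total_length"] = round(tree.total_length, 6)
        if all(cluster_of.values()):
            mono = cluster_groups(tree, cluster_of)
            write_tsv(
                emit(out / "monophyly.tsv"),
                ["Cluster monophyly on the minimum-evolution tree"],
                ["cluster", "monophyletic"],
                sorted(mono.monophyletic.items()),
            )
            manifest["tree.all_clusters_monophyletic"] = mono.all_monophyletic
    else:
        manifest["tree.skipped"] = True

    # --- RSCU / site classes
    if config.stage_siteclass and aln is not None and len(family) >= 1:
        counts = codon_usage(family.records)
        table = rscu(counts, threshold=config.r_threshold)
        write_tsv(
            emit(out / "rscu.tsv"),
            [f"Pooled codon usage and RSCU (R); not_preferable = R <= {config.r_threshold}"],
            ["codon", "amino_acid", "count", "R", "not_preferable"],
            [(c, aa_, counts.get(c, 0),
              f"{table.R[c]:.4f}" if table.R[c] == table.R[c] else "NA",
              int(c in table.not_preferable))
             for c, aa_ in sorted(
                 (c, aa) for aa, cods in SYNONYMOUS_FAMILIES.items() for c in cods)],
        )
        manifest["rscu.n_not_preferable"] = len(table.not_preferable)
        reference_id = next(
            (r.record_id for r in family.records if r.is_reference),
            family.records[0].record_id,
        )
        classes = classify_sites(aln, reference_id, table)
        lm = annotate(aln, family.records, reference_id=reference_id,
                      repeat_max_mismatch=config.repeat_max_mismatch) \
            if config.stage_landmarks else None
        rows, summary = site_report(classes, lm)
        write_tsv(
            emit(out / "site_classes.tsv"),
            [f"Site classification along reference {reference_id} "
             "(residue index and alignment column are 1-based)",
             " ".join(f"{k}={v}" for k, v in summary.items())],
            ["residue", "column", "reference_residue", "class",
             "residues_observed", "codons_observed", "landmarks"],
            rows,
        )
        manifest.update({f"siteclass.{k}": v for k, v in summary.items()})
        if lm is not None:
            write_tsv(
                emit(out / "landmarks.tsv"),
                ["Landmark columns (1-based alignment columns)"],
                ["feature", "value"],
                [("common_cysteines", ",".join(map(str, lm.common_cysteines))),
                 ("glyco_sites", ",".join(map(str, lm.glyco_sites))),
                 ("common_splice_columns", ",".join(map(str, lm.common_splice_columns))),
                 ("repeat_region", lm.repeat_region or "")],
            )
    else:
        manifest["siteclass.skipped"] = True

    # --- manifest
    for p in outputs:
        manifest[f"output.{p.name}"] = _sha256(p)
    with open(out / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}={v}\n")
    return manifest


# ---------------------------------------------------------------------------
# reproduction harness for the deposited data set


def reproduce_deposited(
    embl_dir: str | Path,
    supplementary_aln: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> list[tuple[str, object, object]]:
    """Recompute published statistics from a copy of the deposited records.

    ``embl_dir`` holds EMBL flat files (or FASTA via ``*.fasta``) of the
    TPA records; ``supplementary_aln`` is the published protein alignment
    (aligned FASTA) when available. Returns side-by-side rows
    (quantity, published value, recomputed value); rows whose inputs are
    missing report "NA". A record count other than 211 warns but
    proceeds.
    """
    embl_dir = Path(embl_dir)
    fams = read_embl_dir(embl_dir)
    fasta_paths = sorted(embl_dir.glob("*.fasta")) + sorted(embl_dir.glob("*.fa"))
    records = list(fams.records)
    seen = {r.record_id for r in records}
    for p in fasta_paths:
        records.extend(r for r in read_fasta(p) if r.record_id not in seen)
    for r in records:
        r.validate()
    if len(records) != ref.N_COMPLETE_CDS:
        logger.warning(
            "expected %d deposited records, found %d", ref.N_COMPLETE_CDS, len(records)
        )
    rows: list[tuple[str, object, object]] = [
        ("n_records", ref.N_COMPLETE_CDS, len(records))
    ]

    table = rscu(codon_usage(records))
    rows.append(("n_not_preferable_codons", len(ref.NOT_PREFERABLE_R),
                 len(table.not_preferable)))
    rounded = table.rounded()
    for codon, published in sorted(ref.NOT_PREFERABLE_R.items()):
        rows.append((f"R({codon})", published, rounded.get(codon, "NA")))

    by_cluster = {}
    for r in records:
        by_cluster.setdefault(r.cluster, []).append(r)
    adia = [r for r in by_cluster.get("ADIA", []) if "sapiens" in r.species.lower()]
    if adia:
        rows.append(("human_ADIA_protein_length", ref.ADIA_REFERENCE["n_residues"],
                     len(translate(adia[0]))))
    adir = [r for r in by_cluster.get("ADIR", []) if "sapiens" in r.species.lower()]
    if adir:
        rows.append(("human_ADIR_cds_length_nt", ref.ADIR_CDS_LENGTH_NT,
                     len(adir[0].cds)))

    if supplementary_aln is not None:
        prot_rows = read_aligned_fasta(supplementary_aln)
        aln = thread_nucleotides(prot_rows, records)
        nuc_rows = list(zip(aln.record_ids, aln.nucleotide_rows))
        ident = summarize_alignment(nuc_rows)
        pub = ref.FULL_ALIGNMENT_IDENTITY
        rows.append(("a_bar", pub["a_bar"], round(ident.a_bar, 3)))
        rows.append(("a_max", pub["a_max"], round(ident.a_max, 3)))
        rows.append(("a_min", pub["a_min"], round(ident.a_min, 3)))
        rows.append(("a_bar_ad", pub["a_bar_ad"], round(ident.a_bar_ad, 3)))
        if adia:
            classes = classify_sites(aln, adia[0].record_id, table)
            rows.append(("ADIA_n_invariant", ref.ADIA_REFERENCE["n_invariant"],
                         classes.n_invariant))
            rows.append(("ADIA_n_forward", ref.ADIA_REFERENCE["n_forward"],
                         classes.n_forward))
        # ADIF1 vs ADIF2 on the aligned rows
        adif_human = [
            r.record_id for r in by_cluster.get("ADIF", [])
            if "sapiens" in r.species.lower()
        ]
        if len(adif_human) >= 2:
            from .identity import pairwise_identity

            i, j = (aln.row_index(adif_human[0]), aln.row_index(adif_human[1]))
            a = pairwise_identity(aln.nucleotide_rows[i], aln.nucleotide_rows[j])
            rows.append(("a(ADIF1,ADIF2)", ref.ADIF1_ADIF2_IDENTITY, round(a, 2)))
        if len(nuc_rows) >= 3:
            try:
                tree = me_tree(distances(nuc_rows))
                rows.append(("tree_total_length", "NA", round(tree.total_length, 4)))
            except SaturationError as exc:
                logger.warning("tree skipped: %s", exc)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tsv(
            out_dir / "reproduction.tsv",
            ["Side-by-side comparison: published vs recomputed"],
            ["quantity", "published", "recomputed"],
            rows,
        )
    return rows
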