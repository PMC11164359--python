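"""Orchestration of the full comparative analysis over a set of genomes.

Produces, per run: feature/size, composition/skew, codon usage (RSCU),
codon-bias summary with correlations, ENC-plot and neutrality-plot data,
start/stop codon survey, intergenic-spacer and control-region reports,
and — when per-gene codon alignments or a concatenated alignment are
supplied — per-gene Ka/Ks tables and a K2P/NJ tree with bootstrap supports.
All outputs are TSV/newick text files with a provenance header (inputs,
config hash, seed) so runs are exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import codon_usage as cu
from . import noncoding, phylogeny, selection
from .composition import composition as composition_stats
from .composition import regional_composition
from .genetic_code import INVERTEBRATE_MITO, get_code
from .genome import (
    AnnotatedGenome,
    compute_spacers,
    extract_gene,
    gene_order_signature,
    parse_genbank,
    survey_start_stop,
)

log = logging.getLogger(__name__)

EXIT_OK, EXIT_PARTIAL, EXIT_FATAL = 0, 1, 2


@dataclass
class RunConfig:
    """Configuration of one comparative run (YAML-serializable)."""

    genomes: list[str] = field(default_factory=list)
    alignments_dir: str | None = None
    concat_alignment: str | None = None
    genetic_code: str = INVERTEBRATE_MITO
    kaks_method: str = "ng86_jc"
    bootstrap_reps: int = 1000
    seed: int = 0
    out_dir: str = "mitocomp_out"
    cr_from_annotation: bool = True  # else recompute as rrnS-trnM gap
    enc_mode: str = "concatenate"    # or "per_gene_mean"

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # identical analyses hash equal wherever written
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = (
        f"# mitocomp run: config_hash={config.config_hash()} "
        f"seed={config.seed}\n"
        f"# inputs: {','.join(config.genomes) or '-'}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, na_rep="NA",
                  float_format="%.6g")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def pcg_sequences(genome: AnnotatedGenome) -> dict[str, str]:
    return {
        f.name: extract_gene(genome, f.name)
        for f in genome.features if f.kind == "PCG"
    }


def run_comparative(config: RunConfig) -> int:
    """Run every stage the inputs support; returns an exit code.

    Stage failures are isolated per genome: the run continues and a failure
    manifest is written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failures: list[dict] = []
    genomes: list[AnnotatedGenome] = []
    for path in config.genomes:
        try:
            genomes.extend(parse_genbank(path))
        except Exception as exc:  # isolate per input
            log.error("failed to parse %s: %s", path, exc)
            failures.append({"stage": "parse", "input": str(path),
                             "error": str(exc)})
    if not genomes and not (config.alignments_dir or config.concat_alignment):
        _write_manifest(out, config, failures)
        return EXIT_FATAL

    if genomes:
        _stage_features(genomes, out, config, failures)
        _stage_composition(genomes, out, config, failures)
        _stage_codon_usage(genomes, out, config, failures)
        _stage_noncoding(genomes, out, config, failures)
    if config.alignments_dir:
        _stage_kaks(out, config, failures)
    if config.concat_alignment:
        _stage_tree(out, config, failures)
    elif len(genomes) < 2:
        log.info("phylogeny and pairwise stages skipped: "
                 "fewer than two genomes and no alignment supplied")
    _write_manifest(out, config, failures)
    return EXIT_PARTIAL if failures else EXIT_OK


def _guard(stage: str, failures: list, genome_id: str = "-"):
    def deco(fn):
        try:
            fn()
        except Exception as exc:
            log.error("stage %s failed for %s: %s", stage, genome_id, exc)
            failures.append({"stage": stage, "input": genome_id,
                             "error": str(exc)})
    return deco


def _stage_features(genomes, out: Path, config: RunConfig, failures) -> None:
    rows, spacer_rows, ss_frames = [], [], []
    for g in genomes:
        @_guard("features", failures, g.genome_id)
        def _(g=g):
            order, label, missing = gene_order_signature(g)
            for f in g.features:
                rows.append({
                    "genome": g.genome_id, "taxon": g.taxon,
                    "gene": f.name, "kind": f.kind, "strand": f.strand,
                    "start": f.start, "end": f.end, "length": f.length,
                    "gene_order": label,
                })
            for s in compute_spacers(g):
                spacer_rows.append({
                    "genome": g.genome_id,
                    "upstream": s.upstream_gene,
                    "downstream": s.downstream_gene,
                    "length": s.length,
                    "type": "overlap" if s.is_overlap else "spacer",
                })
            ss = survey_start_stop(g)
            ss.insert(0, "genome", g.genome_id)
            ss_frames.append(ss)
    if rows:
        _write_tsv(pd.DataFrame(rows), out / "features.tsv", config)
    if spacer_rows:
        _write_tsv(pd.DataFrame(spacer_rows), out / "spacers.tsv", config)
    if ss_frames:
        _write_tsv(pd.concat(ss_frames, ignore_index=True),
                   out / "start_stop.tsv", config)


def _resolved_cr(genome: AnnotatedGenome, config: RunConfig):
    """CR sequence per config: annotation if present (default), else the
    rrnS-trnM gap."""
    cr = [f for f in genome.features if f.kind == "CR"]
    if cr and config.cr_from_annotation:
        return genome.region_sequence(cr[0].start, cr[0].end)
    try:
        spacers = compute_spacers(genome)
    except ValueError:
        return None
    for s in spacers:
        if {s.upstream_gene, s.downstream_gene} == {"rrnS", "trnM"}:
            return s.sequence or None
    return genome.region_sequence(cr[0].start, cr[0].end) if cr else None


def _stage_composition(genomes, out: Path, config: RunConfig,
                       failures) -> None:
    frames = []
    for g in genomes:
        @_guard("composition", failures, g.genome_id)
        def _(g=g):
            df = regional_composition(g)
            df.insert(0, "genome", g.genome_id)
            df.insert(1, "taxon", g.taxon)
            frames.append(df)
    if frames:
        _write_tsv(pd.concat(frames, ignore_index=True),
                   out / "composition.tsv", config)


def _stage_codon_usage(genomes, out: Path, config: RunConfig,
                       failures) -> None:
    rscu_rows, summary_rows = [], []
    code = get_code(config.genetic_code)
    for g in genomes:
        @_guard("codon_usage", failures, g.genome_id)
        def _(g=g):
            cds = list(pcg_sequences(g).values())
            if not cds:
                raise ValueError("no protein-coding genes annotated")
            counts = cu.count_codons(cds, code=code)
            rvals = cu.rscu(counts)
            for codon in sorted(rvals):
                rscu_rows.append({
                    "genome": g.genome_id, "codon": codon,
                    "amino_acid": code.translate(codon),
                    "count": counts[codon], "rscu": rvals[codon],
                })
            pos = cu.positional_gc(cds, code=code)
            if config.enc_mode == "per_gene_mean":
                import numpy as np
                per_gene = [
                    cu.enc(cu.count_codons([c], code=code)) for c in cds
                ]
                enc_val = float(np.mean(per_gene))
            else:
                enc_val = cu.enc(counts)
            summary_rows.append({
                "genome": g.genome_id, "taxon": g.taxon,
                "n_codons": counts.total,
                "enc": enc_val,
                "cbi": cu.cbi(counts),
                **{k: pos[k] for k in
                   ("gc1", "gc2", "gc3", "gc12", "gc_all",
                    "at1", "at2", "at3")},
                "enc_expected": cu.enc_null_curve(pos["gc3"] / 100.0),
            })
    if rscu_rows:
        _write_tsv(pd.DataFrame(rscu_rows), out / "rscu.tsv", config)
    if summary_rows:
        df = pd.DataFrame(summary_rows)
        _write_tsv(df, out / "codon_summary.tsv", config)
        if len(df) >= 3:
            pairs = [
                ("gc_all", "enc"), ("gc3", "enc"), ("gc_all", "cbi"),
                ("gc3", "cbi"), ("enc", "cbi"), ("gc3", "gc12"),
            ]
            rows = []
            for x, y in pairs:
                try:
                    r, r2, p = cu.correlation(df[x], df[y])
                except ValueError as exc:
                    log.info("correlation %s~%s skipped: %s", y, x, exc)
                    continue
                rows.append({"x": x, "y": y, "r": r, "r2": r2, "p": p})
            if rows:
                _write_tsv(pd.DataFrame(rows), out / "correlations.tsv",
                           config)


def _stage_noncoding(genomes, out: Path, config: RunConfig,
                     failures) -> None:
    rows = []
    for g in genomes:
        @_guard("noncoding", failures, g.genome_id)
        def _(g=g):
            cr = _resolved_cr(g, config)
            if cr is None:
                log.info("%s: no control region resolvable", g.genome_id)
                return
            for r in noncoding.find_tandem_repeats(cr):
                rows.append({
                    "genome": g.genome_id, "element": "tandem_repeat",
                    "start": r.start, "period": r.period,
                    "copies": round(r.copies, 2),
                    "identity": round(r.identity, 3), "detail": r.consensus,
                })
            for base in "AT":
                for start, length in noncoding.find_runs(cr, base):
                    rows.append({
                        "genome": g.genome_id, "element": f"poly_{base}",
                        "start": start, "period": 1, "copies": length,
                        "identity": 1.0, "detail": base * min(length, 20),
                    })
            rows.append({
                "genome": g.genome_id, "element": "TATA_count",
                "start": -1, "period": 4,
                "copies": noncoding.count_motif(cr, "TATA"),
                "identity": 1.0, "detail": "TATA",
            })
            for h in noncoding.find_hairpins(cr):
                rows.append({
                    "genome": g.genome_id, "element": "hairpin",
                    "start": h.stem_start_5p, "period": h.stem_len,
                    "copies": h.loop_len, "identity": 1.0,
                    "detail": f"stem={h.stem_len},loop={h.loop_len}",
                })
    if rows:
        _write_tsv(pd.DataFrame(rows), out / "noncoding.tsv", config)


def _stage_kaks(out: Path, config: RunConfig, failures) -> None:
    rows = []
    adir = Path(config.alignments_dir)
    for fasta in sorted(adir.glob("*.fa*")):
        gene = fasta.stem
        @_guard("kaks", failures, gene)
        def _(fasta=fasta, gene=gene):
            aln = read_fasta(fasta)
            if len(aln) < 2:
                log.info("%s: fewer than two sequences; omitted", gene)
                return
            summ = selection.gene_kaks_summary(
                aln, code=get_code(config.genetic_code),
                method=config.kaks_method,
                bootstrap_reps=config.bootstrap_reps, seed=config.seed,
            )
            gc = composition_stats("".join(aln.values())).gc_content
            rows.append({"gene": gene, **summ, "gc_content": gc})
    if rows:
        df = pd.DataFrame(rows)
        ratios = df["mean_ratio"].dropna()
        if len(ratios) and (ratios >= 1).any():
            log.warning("Ka/Ks >= 1 for %d gene(s): purifying-selection "
                        "signature not universal in this dataset",
                        int((ratios >= 1).sum()))
        _write_tsv(df, out / "kaks.tsv", config)


def _stage_tree(out: Path, config: RunConfig, failures) -> None:
    @_guard("tree", failures, str(config.concat_alignment))
    def _():
        aln = read_fasta(config.concat_alignment)
        if len(aln) < 3:
            log.info("tree stage skipped: fewer than three sequences")
            return
        dm = phylogeny.distance_matrix(aln)
        ddf = pd.DataFrame(dm.d, columns=dm.taxa)
        ddf.insert(0, "taxon", dm.taxa)
        _write_tsv(ddf, out / "distances.tsv", config)
        tree, dropped = phylogeny.bootstrap_support(
            aln, reps=config.bootstrap_reps, seed=config.seed,
        )
        header = (f"# mitocomp run: config_hash={config.config_hash()} "
                  f"seed={config.seed} dropped_replicates={dropped}\n")
        (out / "tree.nwk").write_text(header + tree.to_newick() + "\n")


def _write_manifest(out: Path, config: RunConfig, failures) -> None:
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "failures": failures,
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
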