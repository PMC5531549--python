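"""End-to-end orchestration: run the characterization stages that have
inputs, emit per-stage TSVs plus a consistent summary JSON."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import (
    binding_classifier,
    consensus_profile,
    domain_model,
    intron_architecture,
    io_formats,
    orthologue_mapper,
    phylogeny,
)

log = logging.getLogger("bhlhkit")


class ConfigError(ValueError):
    """Configuration problems, detected before any compute."""


@dataclass
class PipelineConfig:
    proteins: str | None = None
    hits: str | None = None
    cds: str | None = None
    gff3: str | None = None
    proteins_b: str | None = None
    cds_b: str | None = None
    expression: str | None = None
    groups: str | None = None
    ortholog_table: str | None = None
    min_basic_count: int = 5
    identity_threshold: float = 80.0
    rpkm_threshold: float = 2.0
    fold: float = 2.0
    bootstrap_reps: int = 200
    min_support: float = 50.0
    seed: int = 0
    outdir: str = "bhlhkit_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.proteins or not self.hits:
            raise ConfigError("a characterize run needs at least proteins + hits")
        for name in (
            "proteins", "hits", "cds", "gff3", "proteins_b", "cds_b",
            "expression", "groups", "ortholog_table",
        ):
            path = getattr(self, name)
            if path and not os.path.exists(path):
                raise ConfigError(f"{name} file not found: {path}")
        if not 0 < self.identity_threshold <= 100:
            raise ConfigError("identity_threshold must be in (0, 100]")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be >= 1")
        if not 0 <= self.min_support <= 100:
            raise ConfigError("min_support must be in [0, 100]")
        if self.min_basic_count < 0:
            raise ConfigError("min_basic_count must be >= 0")


def _write_tsv(rows: list[dict], path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_characterize(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; skipped stages are
    logged. Returns (and writes) the summary dict."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    summary: dict = {}

    # --- classification + consensus -------------------------------------
    proteins = io_formats.read_fasta(config.proteins, alphabet="protein")
    hits = io_formats.read_domain_hits(config.hits)
    hits_by_protein = {h.protein_id: h for h in hits}
    rules = binding_classifier.BindingRules(min_basic_count=config.min_basic_count)
    records = []
    for pid, _desc, seq in proteins:
        hit = hits_by_protein.get(pid)
        if hit is None:
            log.warning("no domain hit for %s; skipped", pid)
            continue
        dom = domain_model.extract_domain(seq, hit)
        records.append(domain_model.anchor_to_canonical(dom, protein_id=pid))
    calls = [binding_classifier.classify_binding(r, rules) for r in records]
    summary["family_size"] = len(records)
    summary["binding"] = binding_classifier.summarize_categories(calls)
    _write_tsv(
        binding_classifier.calls_to_rows(calls),
        os.path.join(config.outdir, "binding_calls.tsv"),
    )
    profiles = consensus_profile.column_frequencies(records)
    _write_tsv(
        consensus_profile.profile_rows(profiles),
        os.path.join(config.outdir, "consensus_profile.tsv"),
    )
    summary["conserved_50pct"] = [
        [col, res, round(frac, 4)]
        for col, res, frac in consensus_profile.conserved_residues(profiles, 0.50)
    ]

    # --- intron architecture ---------------------------------------------
    if config.gff3:
        models = io_formats.read_gene_models(config.gff3)
        record_by_protein = {r.protein_id: r for r in records}
        catalog = intron_architecture.default_catalog()
        labels: dict[str, str] = {}
        intron_rows = []
        phase_counts = {0: 0, 1: 0, 2: 0}
        for model in models:
            pid = model.protein_id
            rec = record_by_protein.get(pid)
            hit = hits_by_protein.get(pid)
            if rec is None or hit is None:
                log.warning("no anchored domain for gene %s; skipped", model.gene_id)
                continue
            introns = intron_architecture.domain_introns(
                model, (hit.env_start, hit.env_end), rec
            )
            label = intron_architecture.classify_pattern(introns, catalog)
            labels[model.gene_id] = label
            for r in introns:
                phase_counts[r.phase] += 1
            intron_rows.append(
                {
                    "gene_id": model.gene_id,
                    "n_domain_introns": len(introns),
                    "phases": ",".join(str(r.phase) for r in introns),
                    "pattern": label,
                }
            )
        summary["intron_patterns"] = intron_architecture.pattern_census(labels)
        summary["intron_phase_counts"] = {str(k): v for k, v in phase_counts.items()}
        _write_tsv(intron_rows, os.path.join(config.outdir, "intron_patterns.tsv"))
    else:
        log.info("no gff3 configured; intron stage skipped")

    # --- phylogeny / subfamilies -----------------------------------------
    if len(records) >= 4:
        ids = [r.protein_id for r in records]
        aligned = [r.gapped_sequence() for r in records]
        tree = phylogeny.bootstrap_supports(
            ids, aligned, n_reps=config.bootstrap_reps, seed=config.seed
        )
        subfamilies = phylogeny.extract_subfamilies(tree, config.min_support)
        summary["n_subfamilies"] = sum(1 for c in subfamilies if len(c) > 1)
        summary["subfamilies"] = subfamilies
        with open(os.path.join(config.outdir, "tree.nwk"), "wt") as fh:
            fh.write(phylogeny.to_newick(tree))
    else:
        log.info("fewer than 4 anchored domains; phylogeny stage skipped")

    # --- orthologue mapping -----------------------------------------------
    if config.cds and config.proteins_b and config.cds_b:
        set_a = _gene_records(config.proteins, config.cds)
        set_b = _gene_records(config.proteins_b, config.cds_b)
        pairs = orthologue_mapper.find_orthologs(
            set_a, set_b, threshold=config.identity_threshold
        )
        summary["orthologs"] = {
            "n_pairs": len(pairs),
            "n_syntenic": sum(1 for p in pairs if p.syntenic),
        }
        _write_tsv(
            [vars(p) for p in pairs], os.path.join(config.outdir, "orthologs.tsv")
        )
    elif config.ortholog_table:
        summary["orthologs"] = run_table2_audit(config.ortholog_table)
    else:
        log.info("no orthologue inputs configured; stage skipped")

    # --- expression --------------------------------------------------------
    if config.expression and config.groups:
        from . import expression_analysis as ea

        matrix = io_formats.read_expression_matrix(config.expression, config.groups)
        expressed = ea.expressed_genes(matrix, config.rpkm_threshold)
        specific = ea.tissue_specific(
            matrix, fold=config.fold, floor=config.rpkm_threshold
        )
        summary["expression"] = {
            "n_genes": len(matrix.genes),
            "n_expressed": len(expressed),
            "n_tissue_specific": len(specific),
        }
        rows = [
            {
                "gene": g,
                "expressed": g in expressed,
                "specific_tissue": dict(specific).get(g, ""),
            }
            for g in matrix.genes
        ]
        if matrix.stage_order:
            trends = ea.stage_trend(matrix, min_fold=config.fold)
            summary["expression"]["n_stage_trend"] = sum(
                1 for v in trends.values() if v != "none"
            )
            for row in rows:
                row["stage_trend"] = trends[row["gene"]]
        _write_tsv(rows, os.path.join(config.outdir, "expression_calls.tsv"))
        ea.log_transform(matrix).round(4).to_csv(
            os.path.join(config.outdir, "expression_log2.tsv"), sep="\t"
        )
    else:
        log.info("no expression inputs configured; stage skipped")

    _check_consistency(summary)
    with open(os.path.join(config.outdir, "summary.json"), "wt") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest = {
        "config": asdict(config),
        "config_sha1": hashlib.sha1(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
    }
    with open(os.path.join(config.outdir, "run_manifest.json"), "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def _gene_records(proteins_path, cds_path, locations: dict | None = None):
    proteins = io_formats.read_fasta(proteins_path, alphabet="protein")
    cds = io_formats.read_fasta(cds_path, alphabet="dna")
    cds_by_id = {rid: seq for rid, _d, seq in cds}
    out = []
    for pid, _desc, prot in proteins:
        if pid not in cds_by_id:
            raise ValueError(f"missing CDS for {pid}")
        loc = (locations or {}).get(pid, {})
        out.append(
            orthologue_mapper.GeneRecord(
                gene_id=pid,
                cds=cds_by_id[pid],
                protein=prot,
                chrom=loc.get("chrom"),
                start=loc.get("start"),
                end=loc.get("end"),
            )
        )
    return out


def _check_consistency(summary: dict) -> None:
    binding = summary.get("binding")
    if binding and binding["total"] != summary["family_size"]:
        raise AssertionError("category counts do not sum to the family size")


def run_table2_audit(fixture_path=None) -> dict:
    """Audit an orthologue table: pair count, syntenic count, identity
    floors and the one-to-many genes."""
    path = fixture_path or io_formats.packaged_table2_path()
    rows = io_formats.read_ortholog_table(path)
    n_syntenic = sum(1 for r in rows if r.aa_chrom[1:] == r.bb_chrom[1:])
    from collections import Counter

    aa_counts = Counter(r.aa_gene for r in rows)
    bb_counts = Counter(r.bb_gene for r in rows)
    one_to_many = sorted(
        [g for g, n in aa_counts.items() if n > 1]
        + [g for g, n in bb_counts.items() if n > 1]
    )
    return {
        "n_pairs": len(rows),
        "n_syntenic": n_syntenic,
        "min_cds_identity": min(r.cds_identity_pct for r in rows),
        "min_protein_identity": min(r.protein_identity_pct for r in rows),
        "one_to_many": one_to_many,
    }
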