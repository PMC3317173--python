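"""File-level orchestration of the analysis stages.

Each ``run_*`` function wraps one library stage with file input/output and a
run manifest, so a whole analysis — simulate a dataset, compare a paralog
pair, call duplications on a gene tree — is reproducible bit-for-bit from a
seed. Correlations are serialized with 6 decimal places; an undefined
correlation is written as the literal string ``NA`` together with a reason.
The manifest records the command, parameters, SHA-256 checksums of the
inputs, the seed, the package version and a timestamp; it is the only output
that is not byte-reproducible (the timestamp).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import __version__
from .genome_model import GeneModel, coding_interval, promoter_interval, read_gene_table
from .occupancy import (
    FragmentSet,
    compute_occupancy,
    read_fragments_bed,
    write_profile_bedgraph,
)
from .paralog_tree import (
    copy_number_table,
    label_duplications,
    parse_newick_genetree,
    sister_paralog_pairs,
)
from .profile_similarity import RESAMPLE_MIN, PairSimilarity, compare_paralog_pair
from .synthetic_data import SimConfig, make_paralog_pair, simulate_gene_tree

__all__ = [
    "run_simulate",
    "run_occupancy",
    "run_compare_pair",
    "run_tree_dups",
    "load_config",
]

PathLike = Union[str, Path]


def load_config(source: Union[PathLike, dict, None]) -> dict:
    """Load a flat YAML/JSON config mapping, or pass a dict through."""
    if source is None:
        return {}
    if isinstance(source, dict):
        return dict(source)
    text = Path(source).read_text()
    cfg = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(cfg, dict):
        raise ValueError(f"config {source} must be a mapping")
    return cfg


def _sha256(path: PathLike) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_manifest(
    outdir: Path,
    command: str,
    parameters: dict,
    inputs: Sequence[PathLike] = (),
    seed: Optional[int] = None,
) -> None:
    _write_json(
        {
            "command": command,
            "parameters": parameters,
            "inputs": {str(p): _sha256(p) for p in inputs},
            "seed": seed,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        outdir / "manifest.json",
    )


def _write_genes_tsv(genes: Sequence[GeneModel], path: Path) -> None:
    # emitted 1-based inclusive, the convention read_gene_table expects
    lines = ["gene_id\tchrom\tstrand\tstart\tend\tspecies"]
    lines += [
        f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start + 1}\t{g.end}\t{g.species}"
        for g in genes
    ]
    path.write_text("\n".join(lines) + "\n")


def _write_bed(frags: FragmentSet, path: Path) -> None:
    path.write_text(
        "".join(f"{c}\t{s}\t{e}\n" for c, s, e in frags.fragments)
    )


def _find_gene(genes: Sequence[GeneModel], gene_id: str) -> GeneModel:
    for g in genes:
        if g.gene_id == gene_id:
            return g
    raise KeyError(f"gene {gene_id!r} not found in annotation")


def _rho_str(rho: Optional[float]) -> str:
    return "NA" if rho is None else f"{rho:.6f}"


def _pair_record(pair: PairSimilarity) -> dict:
    rec = asdict(pair)
    for key in ("promoter_rho", "coding_rho"):
        rec[key] = "NA" if rec[key] is None else round(rec[key], 6)
    return rec


# ---------------------------------------------------------------------------


def run_simulate(
    outdir: PathLike,
    seed: int,
    config: Union[PathLike, dict, None] = None,
) -> dict[str, Path]:
    """Generate a full synthetic dataset: genes, fragments, gene tree, truth.

    Config keys (all optional): depth, upstream_len, promoter_occupancy_boost,
    share_promoter, share_coding, coding_len_a, coding_len_b, jitter_sd,
    n_species, dup_species. The config is echoed into truth.json.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim = SimConfig(
        seed=seed,
        depth=int(cfg.get("depth", 100)),
        upstream_len=int(cfg.get("upstream_len", 1000)),
        promoter_occupancy_boost=float(cfg.get("promoter_occupancy_boost", 1.5)),
    )
    gene_a, gene_b, frags, pair_truth = make_paralog_pair(
        sim,
        share_promoter=bool(cfg.get("share_promoter", False)),
        share_coding=bool(cfg.get("share_coding", True)),
        coding_len_a=int(cfg.get("coding_len_a", 1287)),
        coding_len_b=int(cfg.get("coding_len_b", 1287)),
        jitter_sd=float(cfg.get("jitter_sd", 10.0)),
    )
    n_species = int(cfg.get("n_species", 8))
    dup_species = list(cfg.get("dup_species", ["sp01", "sp03"]))
    _, tree_truth = simulate_gene_tree(n_species, dup_species, seed=seed)

    paths = {
        "genes": outdir / "genes.tsv",
        "fragments": outdir / "fragments.bed",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    _write_genes_tsv([gene_a, gene_b], paths["genes"])
    _write_bed(frags, paths["fragments"])
    paths["tree"].write_text(tree_truth["newick"] + "\n")
    _write_json(
        {"config": cfg, "pair": pair_truth, "tree": tree_truth},
        paths["truth"],
    )
    _write_manifest(outdir, "simulate", {"config": cfg}, seed=seed)
    return paths


def run_occupancy(
    bed: PathLike,
    genes: PathLike,
    gene_id: str,
    region: str,
    outdir: PathLike,
    mode: str = "coverage",
    upstream_len: int = 1000,
    genes_format: str = "tsv",
) -> dict[str, Path]:
    """Occupancy profile of one gene region, written as bedGraph + metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene = _find_gene(read_gene_table(str(genes), genes_format), gene_id)
    if region == "promoter":
        interval = promoter_interval(gene, upstream_len)
    elif region == "coding":
        interval = coding_interval(gene)
    else:
        raise ValueError(f"region must be 'promoter' or 'coding', got {region!r}")
    profile = compute_occupancy(read_fragments_bed(str(bed)), interval, mode, gene_id)

    bg_path = outdir / f"{gene_id}_{region}.bedgraph"
    with open(bg_path, "wt") as fh:
        write_profile_bedgraph(profile, fh)
    meta_path = outdir / f"{gene_id}_{region}.json"
    _write_json(
        {
            "gene_id": gene_id,
            "region": region,
            "mode": mode,
            "chrom": interval.chrom,
            "start": interval.start,
            "end": interval.end,
            "strand": interval.strand,
            "truncated": interval.truncated,
            "total_count": int(profile.counts.sum()),
        },
        meta_path,
    )
    _write_manifest(
        outdir,
        "occupancy",
        {"gene_id": gene_id, "region": region, "mode": mode, "upstream_len": upstream_len},
        inputs=[bed, genes],
    )
    return {"bedgraph": bg_path, "metadata": meta_path}


def run_compare_pair(
    bed: PathLike,
    genes: PathLike,
    gene_a: str,
    gene_b: str,
    outdir: PathLike,
    upstream_len: int = 1000,
    mode: str = "coverage",
    length_policy: str = RESAMPLE_MIN,
    genes_format: str = "tsv",
) -> dict[str, Path]:
    """Promoter-ρ / coding-ρ comparison of two paralogs, as TSV + JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_gene_table(str(genes), genes_format)
    pair = compare_paralog_pair(
        _find_gene(table, gene_a),
        _find_gene(table, gene_b),
        read_fragments_bed(str(bed)),
        upstream_len=upstream_len,
        mode=mode,
        length_policy=length_policy,
    )
    rec = _pair_record(pair)
    json_path = outdir / "pair_similarity.json"
    _write_json(rec, json_path)
    tsv_path = outdir / "pair_similarity.tsv"
    header = ["gene_a", "gene_b", "region", "rho", "n", "resampled", "mode", "policy", "reason"]
    rows = [
        [pair.gene_a, pair.gene_b, "promoter", _rho_str(pair.promoter_rho),
         str(pair.promoter_n), str(pair.resampled), pair.mode, pair.length_policy,
         pair.promoter_reason or ""],
        [pair.gene_a, pair.gene_b, "coding", _rho_str(pair.coding_rho),
         str(pair.coding_n), str(pair.resampled), pair.mode, pair.length_policy,
         pair.coding_reason or ""],
    ]
    tsv_path.write_text(
        "\n".join("\t".join(r) for r in [header] + rows) + "\n"
    )
    _write_manifest(
        outdir,
        "compare-pair",
        {
            "gene_a": gene_a,
            "gene_b": gene_b,
            "upstream_len": upstream_len,
            "mode": mode,
            "length_policy": length_policy,
        },
        inputs=[bed, genes],
    )
    return {"tsv": tsv_path, "json": json_path}


def run_tree_dups(
    newick: PathLike,
    outdir: PathLike,
    delimiter: str = "|",
    species_field: int = 0,
    clade_filter: Optional[set[str]] = None,
) -> dict[str, Path]:
    """Copy-number table and duplication report for a species-labeled tree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gtree = parse_newick_genetree(str(newick), delimiter, species_field)
    report = label_duplications(gtree)
    pairs = sister_paralog_pairs(gtree)
    table = copy_number_table(gtree, clade_filter)

    json_path = outdir / "duplications.json"
    _write_json(
        {
            "n_tips": len(gtree),
            "n_species": len(report.copy_table),
            "n_multi_copy": report.n_multi_copy,
            "n_duplications": report.n_duplications,
            "duplication_nodes": sorted(report.duplication_nodes),
            "sister_paralog_pairs": [list(p) for p in pairs],
            "clade_filter": sorted(clade_filter) if clade_filter else None,
        },
        json_path,
    )
    tsv_path = outdir / "copy_table.tsv"
    lines = ["species\tn_copies"]
    lines += [f"{sp}\t{n}" for sp, n in sorted(table.items())]
    tsv_path.write_text("\n".join(lines) + "\n")
    _write_manifest(
        outdir,
        "tree-dups",
        {"delimiter": delimiter, "species_field": species_field},
        inputs=[newick],
    )
    return {"json": json_path, "tsv": tsv_path}
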