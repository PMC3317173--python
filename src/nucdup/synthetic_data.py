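"""Synthetic inputs: nucleosome fragment maps, paralog pairs, gene trees.

Every pipeline stage can be exercised without external data:

* :func:`simulate_fragments` draws mononucleosome-sized fragments (147 ± 10 bp
  by default, clamped ≥ 50) around phased, jittered dyad positions at a
  configurable sequencing depth, plus an optional uniform background.
* :func:`make_paralog_pair` places two genes on disjoint loci and populates
  them from nucleosome architectures that are either shared (same dyad layout,
  independent sampling noise — profiles should correlate strongly) or drawn
  independently (profiles should not). Promoter and coding architectures are
  toggled separately, so "coding conserved, promoter diverged" is a plantable
  ground truth. A promoter occupancy boost ≥ 1 models promoters carrying more
  mapped nucleosomes than coding regions.
* :func:`simulate_gene_tree` builds a random rooted species topology and
  grafts one within-species cherry per requested duplication (no losses), so
  species-overlap detection is provably exact against the planted truth.

All randomness flows from a single seed; outputs are byte-identical across
reruns of the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .genome_model import GeneModel
from .occupancy import FragmentSet
from .paralog_tree import GeneTree, parse_newick_genetree

__all__ = [
    "NucArchitecture",
    "SimConfig",
    "random_architecture",
    "simulate_fragments",
    "make_paralog_pair",
    "simulate_gene_tree",
]

MIN_FRAGMENT_LEN = 50


@dataclass(frozen=True)
class NucArchitecture:
    """A nucleosome layout for one gene region.

    ``dyads`` holds (offset, weight, jitter_sd) triples: the dyad position as
    an offset from the translational start in gene orientation (negative =
    upstream), the occupancy weight in (0, 1] scaling expected depth, and the
    per-nucleosome positional jitter (bp, s.d. of a normal). ``background_rate``
    is uniform fragments per bp over the simulated window.
    """

    dyads: tuple[tuple[int, float, float], ...]
    fragment_len_mean: float = 147.0
    fragment_len_sd: float = 10.0
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dyads", tuple(tuple(d) for d in self.dyads))
        for offset, weight, jitter in self.dyads:
            if not 0.0 < weight <= 1.0:
                raise ValueError(f"dyad weight {weight} not in (0, 1]")
            if jitter < 0:
                raise ValueError("jitter sd must be >= 0")
        if self.fragment_len_mean <= 0:
            raise ValueError("fragment_len_mean must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Global simulation knobs; the seed drives every random draw."""

    seed: int
    depth: int = 100
    upstream_len: int = 1000
    promoter_occupancy_boost: float = 1.5

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.promoter_occupancy_boost < 1.0:
            raise ValueError("promoter_occupancy_boost must be >= 1")


def random_architecture(
    rng: np.random.Generator,
    start_offset: int,
    end_offset: int,
    spacing_range: tuple[int, int] = (150, 185),
    weight_range: tuple[float, float] = (0.3, 1.0),
    jitter_sd: float = 10.0,
    background_rate: float = 0.02,
) -> NucArchitecture:
    """Draw a phased nucleosome array over [start_offset, end_offset).

    One nucleosome repeat length is drawn per architecture from
    ``spacing_range``, the phase is uniform over one repeat, and each dyad
    gets an independent occupancy weight. Defaults reflect typical yeast
    chromatin: ~165 bp repeat, mononucleosome fragments, light background.
    """
    spacing = int(rng.integers(spacing_range[0], spacing_range[1] + 1))
    phase = int(rng.integers(0, spacing))
    dyads = []
    pos = start_offset + phase
    while pos < end_offset:
        weight = float(rng.uniform(*weight_range))
        dyads.append((pos, weight, jitter_sd))
        pos += spacing
    return NucArchitecture(
        dyads=tuple(dyads), background_rate=background_rate
    )


def _draw_fragments(
    rng: np.random.Generator,
    centers: np.ndarray,
    arch: NucArchitecture,
) -> list[tuple[int, int]]:
    n = len(centers)
    lengths = np.rint(
        rng.normal(arch.fragment_len_mean, arch.fragment_len_sd, n)
    ).astype(np.int64)
    lengths = np.maximum(lengths, MIN_FRAGMENT_LEN)
    starts = centers - lengths // 2
    return [
        (int(s), int(s + l)) for s, l in zip(starts, lengths) if s >= 0
    ]


def simulate_fragments(
    arch: NucArchitecture,
    gene: GeneModel,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    depth_scale: float = 1.0,
) -> FragmentSet:
    """Sample nucleosomal fragments around ``arch``'s dyads at ``gene``'s locus.

    Each dyad receives Poisson(depth × depth_scale × weight) fragments whose
    centers are normally jittered around the dyad; background fragments fall
    uniformly over the gene window plus its upstream region. Offsets are in
    gene orientation: on the − strand an offset of +k maps to k bases left of
    the translational start.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sign = 1 if gene.strand == "+" else -1
    origin = gene.translational_start
    frags: list[tuple[str, int, int]] = []
    for offset, weight, jitter in arch.dyads:
        n = int(rng.poisson(cfg.depth * depth_scale * weight))
        if n == 0:
            continue
        centers = np.rint(
            origin + sign * offset + rng.normal(0.0, jitter, n)
        ).astype(np.int64)
        frags.extend(
            (gene.chrom, s, e) for s, e in _draw_fragments(rng, centers, arch)
        )
    if arch.background_rate > 0:
        if gene.strand == "+":
            lo, hi = gene.start - cfg.upstream_len, gene.end
        else:
            lo, hi = gene.start, gene.end + cfg.upstream_len
        lo = max(lo, 0)
        n_bg = int(rng.poisson(arch.background_rate * (hi - lo)))
        if n_bg:
            centers = rng.integers(lo, hi, n_bg).astype(np.int64)
            frags.extend(
                (gene.chrom, s, e)
                for s, e in _draw_fragments(rng, centers, arch)
            )
    return FragmentSet(frags)


def make_paralog_pair(
    cfg: SimConfig,
    share_promoter: bool = False,
    share_coding: bool = True,
    coding_len_a: int = 1287,
    coding_len_b: int = 1287,
    jitter_sd: float = 10.0,
    chrom: str = "chrS",
    locus_gap: int = 5000,
    strand_b: str = "+",
) -> tuple[GeneModel, GeneModel, FragmentSet, dict]:
    """Two paralogous genes on disjoint loci with plantable profile similarity.

    When a region's architecture is shared, both loci are populated from the
    same dyad layout with independent sampling noise; otherwise each locus
    gets an independent draw. The default coding length (1287 bp) matches a
    typical intronless yeast homocitrate synthase ORF. Returns the two gene
    models, the pooled fragment set, and a truth record.
    """
    rng = np.random.default_rng(cfg.seed)
    up = cfg.upstream_len
    start_a = up + 500
    gene_a = GeneModel("geneA", chrom, "+", start_a, start_a + coding_len_a, "simulated")
    start_b = gene_a.end + up + locus_gap
    if strand_b == "+":
        gene_b = GeneModel("geneB", chrom, "+", start_b, start_b + coding_len_b, "simulated")
    else:
        # promoter of a − strand gene sits to the right of the coding span
        gene_b = GeneModel("geneB", chrom, "-", start_b, start_b + coding_len_b, "simulated")

    prom_a = random_architecture(rng, -up, 0, jitter_sd=jitter_sd)
    cod_a = random_architecture(rng, 0, coding_len_a, jitter_sd=jitter_sd)
    prom_b = prom_a if share_promoter else random_architecture(rng, -up, 0, jitter_sd=jitter_sd)
    cod_b = cod_a if share_coding else random_architecture(rng, 0, coding_len_b, jitter_sd=jitter_sd)

    boost = cfg.promoter_occupancy_boost
    frags: list[tuple[str, int, int]] = []
    for gene, prom_arch, cod_arch in (
        (gene_a, prom_a, cod_a),
        (gene_b, prom_b, cod_b),
    ):
        frags.extend(
            simulate_fragments(prom_arch, gene, cfg, rng, depth_scale=boost).fragments
        )
        frags.extend(simulate_fragments(cod_arch, gene, cfg, rng).fragments)

    truth = {
        "share_promoter": share_promoter,
        "share_coding": share_coding,
        "seed": cfg.seed,
        "depth": cfg.depth,
        "jitter_sd": jitter_sd,
        "promoter_occupancy_boost": boost,
        "architectures": {
            "promoter_a": prom_a.dyads,
            "coding_a": cod_a.dyads,
            "promoter_b": prom_b.dyads,
            "coding_b": cod_b.dyads,
        },
    }
    return gene_a, gene_b, FragmentSet(frags), truth


# ---------------------------------------------------------------------------
# gene trees with planted duplications


def _random_topology(rng: np.random.Generator, species: Sequence[str]) -> dict:
    nodes: list[dict] = [
        {"species": sp, "gene": "g1"} for sp in species
    ]
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        nodes.append({"children": [a, b]})
    return nodes[0]


def _collect_tips(node: dict, out: list[dict]) -> None:
    if "children" in node:
        for child in node["children"]:
            _collect_tips(child, out)
    else:
        out.append(node)


def _to_newick(node: dict) -> str:
    if "children" in node:
        return "(" + ",".join(_to_newick(c) for c in node["children"]) + ")"
    return f"{node['species']}|{node['gene']}"


def _planted_pairs(node: dict, out: list[tuple[str, str, str]]) -> None:
    if "children" not in node:
        return
    kids = node["children"]
    if len(kids) == 2 and all("children" not in k for k in kids):
        if kids[0]["species"] == kids[1]["species"]:
            g1, g2 = sorted([kids[0]["gene"], kids[1]["gene"]])
            out.append((kids[0]["species"], g1, g2))
            return
    for child in kids:
        _planted_pairs(child, out)


def simulate_gene_tree(
    n_species: int,
    dup_events: Sequence[str] = (),
    seed: int = 0,
    species_names: Optional[Sequence[str]] = None,
) -> tuple[GeneTree, dict]:
    """Random rooted gene tree with planted within-species duplications.

    ``dup_events`` lists the species receiving a duplication (repeats allowed:
    each entry splits one randomly chosen existing gene copy of that species
    into a cherry). No losses are simulated, so the species-overlap criterion
    recovers exactly ``len(dup_events)`` duplication nodes. Returns the parsed
    tree and a truth record with the planted count, the final within-species
    cherry pairs, and the Newick string.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if species_names is None:
        species_names = [f"sp{i + 1:02d}" for i in range(n_species)]
    elif len(species_names) != n_species:
        raise ValueError("species_names length must equal n_species")
    known = set(species_names)
    for sp in dup_events:
        if sp not in known:
            raise ValueError(f"duplication requested for unknown species {sp!r}")

    rng = np.random.default_rng(seed)
    root = _random_topology(rng, species_names)
    counters = {sp: 1 for sp in species_names}
    for sp in dup_events:
        tips: list[dict] = []
        _collect_tips(root, tips)
        candidates = [t for t in tips if t["species"] == sp]
        target = candidates[int(rng.integers(0, len(candidates)))]
        c = counters[sp]
        child_a = {"species": sp, "gene": f"g{c + 1}"}
        child_b = {"species": sp, "gene": f"g{c + 2}"}
        counters[sp] = c + 2
        # split the chosen tip in place into a within-species cherry
        target.pop("species")
        target.pop("gene")
        target["children"] = [child_a, child_b]

    newick = _to_newick(root) + ";"
    pairs: list[tuple[str, str, str]] = []
    _planted_pairs(root, pairs)
    truth = {
        "n_species": n_species,
        "n_duplications": len(dup_events),
        "dup_species": list(dup_events),
        "pairs": sorted(pairs),
        "newick": newick,
        "seed": seed,
    }
    return parse_newick_genetree(newick), truth
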