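"""Synthetic WGBS study generator with known ground truth.

Produces a complete toy experiment for a two-condition developing-stem
design: a random reference genome with gene and transposable-element
annotations, per-cytosine bisulfite call tables for each condition and
biological replicate, an unmethylated lambda spike-in with a small
non-conversion probability, and per-gene expression (FPKM) tables whose
rank correlation with gene-body CG methylation is set by a Gaussian
copula.

The generative model, per cytosine site:

* a *true methylation level* is drawn from a per-context Beta mixture
  (bimodal for CG/CHG, low-skewed for CHH), shifted additively inside
  transposable elements and inside planted differential regions (second
  condition only), then clamped to [0, 1];
* per replicate, read depth is Poisson with the configured mean, and the
  methylated-read count is Binomial with success probability
  ``level * (1 - nc) + (1 - level) * nc`` where ``nc`` is the bisulfite
  non-conversion rate — unmethylated molecules escape conversion with
  probability ``nc`` and methylated molecules are mis-read at the same
  small rate.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as mio

__all__ = [
    "BetaMixture", "GeneStructure", "PlantedDMR", "SyntheticConfig",
    "AnnotatedGenome", "PlacementError", "generate_genome",
    "generate_methylome", "generate_lambda_calls", "generate_expression",
    "simulate_study",
]


class PlacementError(ValueError):
    """Genome too short to place the requested genes/TEs."""


@dataclass(frozen=True)
class BetaMixture:
    """Mixture of Beta components parameterized by (mean, concentration)."""
    weights: tuple[float, ...]
    means: tuple[float, ...]
    concentrations: tuple[float, ...]

    def validate(self, name: str) -> None:
        if not (len(self.weights) == len(self.means) == len(self.concentrations)):
            raise ValueError(f"{name}: mixture component lists differ in length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"{name}: mixture weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValueError(f"{name}: negative mixture weight")
        if any(not 0.0 <= m <= 1.0 for m in self.means):
            raise ValueError(f"{name}: component means must be in [0,1]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        a = np.array([m * c for m, c in zip(self.means, self.concentrations)])
        b = np.array([(1 - m) * c for m, c in zip(self.means, self.concentrations)])
        out = np.empty(n)
        degenerate = (a == 0) | (b == 0)  # point masses at 0 or 1
        for k in range(len(self.weights)):
            mask = comp == k
            if degenerate[k]:
                out[mask] = self.means[k]
            else:
                out[mask] = rng.beta(a[k], b[k], size=int(mask.sum()))
        return out


@dataclass(frozen=True)
class GeneStructure:
    """Ranges (inclusive) for the drawn gene architecture, in bp."""
    n_exons: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (100, 400)
    intron_length: tuple[int, int] = (80, 300)
    utr5_length: int = 150
    utr3_length: int = 200


@dataclass(frozen=True)
class PlantedDMR:
    """A ground-truth differential region: the second condition's true levels
    are shifted by ``delta`` (clamped to [0,1]) for sites of ``context``
    (``ALL`` matches every context) inside [start, end) of ``chrom``."""
    chrom: str
    start: int
    end: int
    context: str = "CG"
    delta: float = 0.4

    @property
    def direction(self) -> str:
        return "hyper" if self.delta > 0 else "hypo"


# Fig.3-style per-context defaults: a near-zero "unmethylated" mode, a broad
# intermediate mode, and a high mode, with the low/high masses matching the
# reported ~45%/40% (CG), ~65%/24% (CHG) and ~83%/<1% (CHH) bin occupancies.
DEFAULT_CONTEXT_METHYLATION: dict[str, BetaMixture] = {
    "CG": BetaMixture((0.45, 0.15, 0.40), (0.005, 0.50, 0.95), (200.0, 6.0, 30.0)),
    "CHG": BetaMixture((0.65, 0.11, 0.24), (0.005, 0.50, 0.95), (200.0, 6.0, 30.0)),
    "CHH": BetaMixture((0.83, 0.15, 0.02), (0.005, 0.30, 0.95), (200.0, 6.0, 30.0)),
}

DEFAULT_TE_CLASS_WEIGHTS = {"LTR": 0.5, "LINE": 0.2, "SINE": 0.1, "DNA": 0.2}

# Superfamily labels per class (labels only, no sequence model).
TE_SUPERFAMILIES = {
    "LTR": ("Gypsy", "Copia", "Caulimovirus"),
    "LINE": ("L1",),
    "SINE": ("Unknown",),
    "DNA": ("CMC-EnSpm", "hAT-Tag1", "hAT-Tip100"),
}


@dataclass
class SyntheticConfig:
    seed: int = 0
    genome_length: int = 200_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.34
    n_genes: int = 20
    gene_structure: GeneStructure = field(default_factory=GeneStructure)
    n_tes: int = 15
    te_length: tuple[int, int] = (300, 2000)
    te_class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TE_CLASS_WEIGHTS))
    context_methylation: dict[str, BetaMixture] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_METHYLATION))
    te_methylation_boost: float = 0.3
    depth_mean: float = 30.0
    n_replicates: int = 3
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    lambda_length: int = 48_502
    non_conversion_rate: float = 0.0049
    expression_copula_rho: float = 0.25
    deg_fraction: float = 0.10
    deg_log2fc_range: tuple[float, float] = (1.0, 3.0)
    expression_replicate_sigma: float = 0.10
    condition_names: tuple[str, str] = ("PS", "TS")

    def validate(self) -> None:
        for name, p in [("gc_fraction", self.gc_fraction),
                        ("non_conversion_rate", self.non_conversion_rate),
                        ("deg_fraction", self.deg_fraction)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if abs(self.expression_copula_rho) > 1.0:
            raise ValueError("expression_copula_rho must lie in [-1, 1]")
        if abs(sum(self.te_class_weights.values()) - 1.0) > 1e-9:
            raise ValueError("te_class_weights must sum to 1")
        for ctx, mix in self.context_methylation.items():
            mix.validate(f"context_methylation[{ctx}]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        sizes = self.chrom_sizes()
        spans: dict[str, list[tuple[int, int]]] = {}
        for d in self.planted_dmrs:
            if d.chrom not in sizes:
                raise ValueError(f"planted DMR on unknown chromosome {d.chrom}")
            if not (0 <= d.start < d.end <= sizes[d.chrom]):
                raise ValueError(f"planted DMR {d} outside the genome")
            for s, e in spans.setdefault(d.chrom, []):
                if d.start < e and s < d.end:
                    raise ValueError("planted DMRs overlap")
            spans[d.chrom].append((d.start, d.end))

    def chrom_sizes(self) -> dict[str, int]:
        base = self.genome_length // self.n_chromosomes
        sizes = {f"chr{i + 1}": base for i in range(self.n_chromosomes)}
        sizes[f"chr{self.n_chromosomes}"] += self.genome_length % self.n_chromosomes
        return sizes


@dataclass
class AnnotatedGenome:
    sequences: dict[str, str]
    genes: pd.DataFrame        # gene_id, chrom, start, end, strand
    gene_parts: pd.DataFrame   # gene_id, kind, start, end
    tes: pd.DataFrame          # te_id, chrom, start, end, strand, te_class, te_superfamily

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _rng(seed: int, *key: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return np.random.Generator(np.random.PCG64(ss))


_STREAM_GENOME, _STREAM_TRUTH, _STREAM_COUNTS, _STREAM_LAMBDA, _STREAM_EXPR = range(5)


# ---------------------------------------------------------------------------
# Genome + annotations
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, size=length, p=probs).tobytes().decode("ascii")


def _draw_gene_parts(rng: np.random.Generator, gs: GeneStructure
                     ) -> tuple[int, list[tuple[str, int, int]]]:
    """Return (gene_length, parts in transcript orientation, 0-based offsets)."""
    n_ex = int(rng.integers(gs.n_exons[0], gs.n_exons[1] + 1))
    exons = rng.integers(gs.exon_length[0], gs.exon_length[1] + 1, size=n_ex)
    introns = (rng.integers(gs.intron_length[0], gs.intron_length[1] + 1,
                            size=n_ex - 1) if n_ex > 1 else np.array([], int))
    parts: list[tuple[str, int, int]] = []
    off = 0
    parts.append(("five_prime_UTR", off, off + gs.utr5_length))
    off += gs.utr5_length
    for i, ex in enumerate(exons):
        parts.append(("exon", off, off + int(ex)))
        parts.append(("CDS", off, off + int(ex)))
        off += int(ex)
        if i < len(introns):
            off += int(introns[i])
    parts.append(("three_prime_UTR", off, off + gs.utr3_length))
    off += gs.utr3_length
    return off, parts


def generate_genome(config: SyntheticConfig) -> AnnotatedGenome:
    """Generate the reference sequences and gene/TE annotations.

    Genes are placed non-overlapping with randomized intergenic gaps; TEs
    are placed in intergenic space by rejection sampling.  Raises
    :class:`PlacementError` when the genome cannot hold the request.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_GENOME)
    sizes = config.chrom_sizes()
    sequences = {c: _random_sequence(rng, n, config.gc_fraction)
                 for c, n in sizes.items()}

    chroms = list(sizes)
    gene_rows, part_rows = [], []
    min_gap = 200
    # round-robin gene assignment, proportional-ish to chromosome count
    per_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for i in range(config.n_genes):
        per_chrom[chroms[i % len(chroms)]].append(i)
    for chrom, idxs in per_chrom.items():
        if not idxs:
            continue
        drawn = [_draw_gene_parts(rng, config.gene_structure) for _ in idxs]
        total = sum(length for length, _ in drawn)
        free = sizes[chrom] - total - (len(idxs) + 1) * min_gap
        if free < 0:
            raise PlacementError(
                f"cannot place {len(idxs)} genes on {chrom} "
                f"({sizes[chrom]} bp available, {total} bp of gene needed)")
        w = rng.random(len(idxs) + 1)
        extra = np.floor(free * w / w.sum()).astype(int)
        pos = 0
        for k, (i, (length, parts)) in enumerate(zip(idxs, drawn)):
            pos += min_gap + int(extra[k])
            start, end = pos, pos + length
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{i + 1:04d}"
            gene_rows.append((gid, chrom, start, end, strand))
            for kind, a, b in parts:
                if strand == "+":
                    part_rows.append((gid, kind, start + a, start + b))
                else:  # mirror transcript orientation onto the genome
                    part_rows.append((gid, kind, end - b, end - a))
            pos = end
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "chrom", "start", "end", "strand"])
    gene_parts = (pd.DataFrame(part_rows, columns=["gene_id", "kind", "start", "end"])
                  .sort_values(["gene_id", "start", "kind"]).reset_index(drop=True))

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for g in genes.itertuples():
        occupied[g.chrom].append((g.start, g.end))
    te_rows = []
    classes = list(config.te_class_weights)
    cw = np.array([config.te_class_weights[c] for c in classes])
    chrom_p = np.array([sizes[c] for c in chroms], float)
    chrom_p /= chrom_p.sum()
    tries = 0
    for i in range(config.n_tes):
        while True:
            tries += 1
            if tries > 200 * max(config.n_tes, 1):
                raise PlacementError("cannot place TEs in the remaining intergenic space")
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            length = int(rng.integers(config.te_length[0], config.te_length[1] + 1))
            if length >= sizes[chrom]:
                continue
            start = int(rng.integers(0, sizes[chrom] - length))
            end = start + length
            if any(start < e and s < end for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            cls = classes[int(rng.choice(len(classes), p=cw))]
            sf = TE_SUPERFAMILIES[cls][int(rng.integers(len(TE_SUPERFAMILIES[cls])))]
            strand = "+" if rng.random() < 0.5 else "-"
            te_rows.append((f"te{i + 1:04d}", chrom, start, end, strand, cls, sf))
            break
    tes = pd.DataFrame(te_rows, columns=["te_id", "chrom", "start", "end",
                                         "strand", "te_class", "te_superfamily"])
    return AnnotatedGenome(sequences, genes, gene_parts, tes)


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def true_levels(config: SyntheticConfig, genome: AnnotatedGenome,
                condition_index: int,
                context_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ground-truth per-site methylation levels for one condition.

    The base level (context mixture + TE boost) is shared between the two
    conditions; condition 1 additionally applies the planted DMR deltas.
    Returns chrom, pos, strand, context, true_level.
    """
    if condition_index not in (0, 1):
        raise ValueError("condition_index must be 0 or 1")
    if context_table is None:
        context_table = mio.classify_contexts(genome.sequences)
    sites = (context_table.sort_values(["chrom", "pos", "strand"])
             .reset_index(drop=True).copy())
    rng = _rng(config.seed, _STREAM_TRUTH)
    level = np.empty(len(sites))
    ctx_arr = sites["context"].to_numpy()
    for ctx in mio.CONTEXTS:  # fixed order keeps draws reproducible
        mask = ctx_arr == ctx
        level[mask] = config.context_methylation[ctx].sample(rng, int(mask.sum()))
    if config.te_methylation_boost and len(genome.tes):
        in_te = _in_intervals(sites, genome.tes)
        level[in_te] = np.clip(level[in_te] + config.te_methylation_boost, 0.0, 1.0)
    if condition_index == 1:
        for d in config.planted_dmrs:
            mask = ((sites["chrom"].to_numpy() == d.chrom)
                    & (sites["pos"].to_numpy() >= d.start)
                    & (sites["pos"].to_numpy() < d.end))
            if d.context != "ALL":
                mask &= ctx_arr == d.context
            level[mask] = np.clip(level[mask] + d.delta, 0.0, 1.0)
    sites["true_level"] = level
    return sites


def _in_intervals(sites: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(sites), bool)
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    for c, sub in intervals.groupby("chrom", sort=False):
        cm = chrom == c
        p = pos[cm]
        hit = np.zeros(len(p), bool)
        for iv in sub.itertuples():
            hit |= (p >= iv.start) & (p < iv.end)
        mask[cm] = hit
    return mask


def generate_methylome(config: SyntheticConfig, genome: AnnotatedGenome,
                       condition_index: int,
                       context_table: pd.DataFrame | None = None
                       ) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Simulate per-replicate call tables for one condition.

    Returns ``(truth, replicates)`` where truth carries the per-site true
    level and each replicate is a call table (sites with zero coverage in
    that replicate are omitted, as a methylation extractor would).
    """
    truth = true_levels(config, genome, condition_index, context_table)
    nc = config.non_conversion_rate
    p_read = truth["true_level"].to_numpy() * (1 - nc) \
        + (1 - truth["true_level"].to_numpy()) * nc
    replicates = []
    for rep in range(config.n_replicates):
        rng = _rng(config.seed, _STREAM_COUNTS, condition_index, rep)
        total = rng.poisson(config.depth_mean, size=len(truth))
        mc = rng.binomial(total, p_read)
        df = truth[["chrom", "pos", "strand", "context"]].copy()
        df["mc_count"] = mc
        df["total_count"] = total
        replicates.append(df[df["total_count"] > 0].reset_index(drop=True))
    return truth, replicates


def generate_lambda_calls(config: SyntheticConfig, condition_index: int = 0
                          ) -> tuple[str, pd.DataFrame]:
    """Simulate the unmethylated lambda spike-in for one sample.

    Every lambda cytosine has true level 0; methylated counts are pure
    non-conversion noise.  Coverage is pooled over the sample's replicates
    (Poisson with mean ``depth_mean * n_replicates``).  Returns the lambda
    sequence and its call table (chrom ``lambda``).
    """
    if config.lambda_length <= 0:
        raise ValueError("lambda_length must be positive")
    rng = _rng(config.seed, _STREAM_LAMBDA, condition_index)
    seq = _random_sequence(rng, config.lambda_length, 0.5)
    ctx = mio.classify_contexts({"lambda": seq})
    ctx = ctx.sort_values(["pos", "strand"]).reset_index(drop=True)
    total = rng.poisson(config.depth_mean * config.n_replicates, size=len(ctx))
    mc = rng.binomial(total, config.non_conversion_rate)
    out = ctx.copy()
    out["mc_count"] = mc
    out["total_count"] = total
    return seq, out[out["total_count"] > 0].reset_index(drop=True)


def select_dmr_regions(genome: AnnotatedGenome, n: int, length: int = 600,
                       context: str = "CG", min_sites: int = 10,
                       delta: float = 0.4, spacing: int = 2000,
                       context_table: pd.DataFrame | None = None
                       ) -> list[PlantedDMR]:
    """Pick ``n`` non-overlapping regions dense enough in ``context`` sites
    to plant differential regions with a guaranteed site count.

    Candidate windows tile each chromosome at ``length + spacing`` intervals;
    a window qualifies when it holds at least ``min_sites`` symmetric-site
    units (+-strand positions for CG/CHG, both strands for CHH).  Selection
    is deterministic given the genome.  Raises when fewer than ``n``
    candidates qualify.
    """
    if context_table is None:
        context_table = mio.classify_contexts(genome.sequences)
    sub = context_table[context_table["context"] == context]
    if context in ("CG", "CHG"):
        sub = sub[sub["strand"] == "+"]
    chosen: list[PlantedDMR] = []
    for chrom, size in genome.chrom_sizes.items():
        pos = np.sort(sub[sub["chrom"] == chrom]["pos"].to_numpy())
        for start in range(0, size - length, length + spacing):
            if len(chosen) == n:
                return chosen
            count = np.searchsorted(pos, start + length) - np.searchsorted(pos, start)
            if count >= min_sites:
                chosen.append(PlantedDMR(chrom, start, start + length,
                                         context, delta))
    if len(chosen) < n:
        raise PlacementError(
            f"only {len(chosen)} of {n} requested regions hold >= {min_sites} "
            f"{context} sites")
    return chosen


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gene_body_true_methylation(truth: pd.DataFrame, genes: pd.DataFrame,
                               context: str = "CG") -> pd.Series:
    """Mean ground-truth level of ``context`` sites inside each gene body."""
    sub = truth[truth["context"] == context]
    vals = {}
    for g in genes.itertuples():
        m = sub[(sub["chrom"] == g.chrom) & (sub["pos"] >= g.start)
                & (sub["pos"] < g.end)]["true_level"]
        vals[g.gene_id] = float(m.mean()) if len(m) else np.nan
    s = pd.Series(vals, name="gene_body_methylation")
    return s.fillna(s.mean())


def generate_expression(config: SyntheticConfig, gene_body_meth: pd.Series
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw FPKM values rank-correlated with gene-body CG methylation.

    A Gaussian copula links the methylation ranks to log-FPKM: the normal
    score of each gene's methylation rank is mixed with independent noise
    using the Pearson coefficient ``r = 2 sin(pi * rho / 6)`` so that the
    *population* Spearman correlation equals ``expression_copula_rho``.
    A ``deg_fraction`` of genes receive a condition-1 log2 fold-change drawn
    uniformly from ``deg_log2fc_range`` with random sign.

    Returns ``(expression, deg_truth)``: expression has one row per
    gene x sample x replicate (column ``fpkm``), deg_truth records the true
    differential state per gene.
    """
    rho = config.expression_copula_rho
    if abs(rho) > 1.0:
        raise ValueError("expression_copula_rho must lie in [-1, 1]")
    rng = _rng(config.seed, _STREAM_EXPR)
    genes = gene_body_meth.index.to_numpy()
    n = len(genes)
    from scipy import stats as sps
    ranks = sps.rankdata(gene_body_meth.to_numpy(), method="average")
    z_meth = sps.norm.ppf((ranks - 0.5) / n)
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    eps = rng.standard_normal(n)
    z_expr = r * z_meth + np.sqrt(max(0.0, 1.0 - r * r)) * eps
    fpkm0 = 10.0 ** (0.5 + 1.0 * z_expr)

    n_deg = int(round(config.deg_fraction * n))
    deg_idx = rng.choice(n, size=n_deg, replace=False) if n_deg else np.array([], int)
    lfc = np.zeros(n)
    if n_deg:
        mag = rng.uniform(*config.deg_log2fc_range, size=n_deg)
        sign = rng.choice([-1.0, 1.0], size=n_deg)
        lfc[deg_idx] = mag * sign
    fpkm1 = fpkm0 * 2.0 ** lfc

    rows = []
    for cond, fpkm in zip(config.condition_names, (fpkm0, fpkm1)):
        for rep in range(config.n_replicates):
            noise = np.exp(rng.normal(0.0, config.expression_replicate_sigma, n)) \
                if config.expression_replicate_sigma > 0 else 1.0
            rows.append(pd.DataFrame({
                "gene_id": genes, "sample": cond, "replicate": rep + 1,
                "fpkm": fpkm * noise}))
    expression = pd.concat(rows, ignore_index=True)
    is_deg = np.zeros(n, bool)
    is_deg[deg_idx] = True
    deg_truth = pd.DataFrame({
        "gene_id": genes, "is_deg": is_deg, "log2fc": lfc,
        "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
    })
    return expression, deg_truth


# ---------------------------------------------------------------------------
# Whole-study driver
# ---------------------------------------------------------------------------

def simulate_study(config: SyntheticConfig, outdir: str | os.PathLike
                   ) -> dict[str, object]:
    """Generate and write the full toy study; return a manifest of paths.

    Writes genome.fa, lambda.fa, genes.gff3, tes.gff3, per-sample lambda and
    replicate call tables, expression.tsv and truth.json (ground-truth
    summary: per-context true mean levels, planted DMRs, true DEGs, seed).
    """
    config.validate()
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    genome = generate_genome(config)
    mio.write_fasta(genome.sequences, os.path.join(outdir, "genome.fa"))
    mio.write_gff3(genome.genes, genome.gene_parts, genome.tes,
                   os.path.join(outdir, "genes.gff3"),
                   os.path.join(outdir, "tes.gff3"))
    context_table = mio.classify_contexts(genome.sequences)

    manifest: dict[str, object] = {
        "seed": config.seed,
        "genome_fasta": "genome.fa", "gene_gff3": "genes.gff3",
        "te_gff3": "tes.gff3", "samples": {},
    }
    truth_summary: dict[str, object] = {
        "seed": config.seed,
        "planted_dmrs": [dataclasses.asdict(d) for d in config.planted_dmrs],
        "true_mean_levels": {},
    }
    truth0 = None
    for cond_idx, sample in enumerate(config.condition_names):
        truth, reps = generate_methylome(config, genome, cond_idx, context_table)
        if cond_idx == 0:
            truth0 = truth
        lam_seq, lam_calls = generate_lambda_calls(config, cond_idx)
        if cond_idx == 0:
            mio.write_fasta({"lambda": lam_seq}, os.path.join(outdir, "lambda.fa"))
        lam_path = f"lambda_{sample}.tsv"
        mio.write_calls(lam_calls, os.path.join(outdir, lam_path))
        rep_paths = []
        for i, rep in enumerate(reps):
            p = f"calls_{sample}_rep{i + 1}.tsv"
            mio.write_calls(rep, os.path.join(outdir, p))
            rep_paths.append(p)
        manifest["samples"][sample] = {"replicates": rep_paths, "lambda": lam_path}
        truth_summary["true_mean_levels"][sample] = {
            ctx: float(truth.loc[truth["context"] == ctx, "true_level"].mean())
            for ctx in mio.CONTEXTS}

    gb_meth = gene_body_true_methylation(truth0, genome.genes)
    expression, deg_truth = generate_expression(config, gb_meth)
    expression.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t", index=False)
    truth_summary["true_degs"] = deg_truth[deg_truth["is_deg"]]["gene_id"].tolist()
    truth_summary["gene_body_true_methylation"] = {
        k: float(v) for k, v in gb_meth.items()}
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth_summary, fh, indent=1, sort_keys=True)
    manifest["expression"] = "expression.tsv"
    manifest["truth"] = "truth.json"
    return manifest
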