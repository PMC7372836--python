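"""Readers/writers for the on-disk formats and reference-based context classification.

Coordinate convention: everything in memory is 0-based, half-open.  The
on-disk formats (call-table TSV, GFF3) are 1-based inclusive and are
converted at the boundary.

A *call table* is a 6-column TSV with header::

    chrom  pos  strand  context  mc_count  total_count

where ``pos`` is the 1-based position of the cytosine on the + strand
reference, ``strand`` is ``+`` or ``-``, ``context`` is one of CG/CHG/CHH,
``mc_count`` the number of reads supporting methylation (unconverted C)
and ``total_count`` the total read coverage at the site.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pyfaidx
from intervaltree import IntervalTree

CONTEXTS = ("CG", "CHG", "CHH")
CALL_COLUMNS = ["chrom", "pos", "strand", "context", "mc_count", "total_count"]

_VALID_BASES = frozenset(b"ACGTN")


class CallTableError(ValueError):
    """A malformed row in a cytosine call table."""


class GenomeError(ValueError):
    """Invalid reference sequence content."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into an in-memory ``{name: sequence}`` mapping."""
    with pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Cytosine context classification
# ---------------------------------------------------------------------------

def classify_contexts(sequences: Mapping[str, str],
                      drop_undefined: bool = True) -> pd.DataFrame:
    """Classify every cytosine on both strands of a reference into CG/CHG/CHH.

    The context is read 5'->3' on the cytosine's own strand: a + strand C at
    ``i`` looks at ``i+1, i+2``; a - strand C (a G on the + strand at ``i``)
    looks at the complements of ``i-1, i-2``.  CG is decided from the single
    next base, so a CpG dyad at a chromosome edge still classifies and the
    number of CG sites is identical on the two strands for any sequence.
    CHG/CHH require two downstream bases; when a required base is missing
    (chromosome end) or is N the context is undefined and, by default, the
    site is dropped.

    Returns a DataFrame with columns chrom, pos (0-based), strand, context.
    """
    frames = []
    for chrom, seq in sequences.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise GenomeError(
                f"non-IUPAC character {chr(arr[i])!r} in {chrom} at position {i + 1}")
        frames.append(_classify_one(chrom, arr))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    out = pd.concat(frames, ignore_index=True)
    if drop_undefined:
        out = out.dropna(subset=["context"]).reset_index(drop=True)
    return out


def _classify_one(chrom: str, arr: np.ndarray) -> pd.DataFrame:
    C, G, N = ord("C"), ord("G"), ord("N")
    L = len(arr)
    # pad with N so off-end lookups read as undefined
    padded = np.concatenate([np.full(2, N, np.uint8), arr, np.full(2, N, np.uint8)])

    def ctx(pos: np.ndarray, d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
        """d1/d2 are the two downstream bases read 5'->3' on the C's strand."""
        out = np.full(pos.shape, None, dtype=object)
        valid1 = d1 != N
        out[valid1 & (d1 == G)] = "CG"
        h1 = valid1 & (d1 != G)
        valid2 = d2 != N
        out[h1 & valid2 & (d2 == G)] = "CHG"
        out[h1 & valid2 & (d2 != G)] = "CHH"
        return out

    plus = np.flatnonzero(arr == C)
    d1 = padded[plus + 3]
    d2 = padded[plus + 4]
    ctx_plus = ctx(plus, d1, d2)

    minus = np.flatnonzero(arr == G)
    # downstream on - strand: complement of reference at i-1, i-2
    comp = np.full(256, N, np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    m1 = comp[padded[minus + 1]]
    m2 = comp[padded[minus]]
    ctx_minus = ctx(minus, m1, m2)

    return pd.DataFrame({
        "chrom": chrom,
        "pos": np.concatenate([plus, minus]),
        "strand": np.concatenate([np.full(len(plus), "+"), np.full(len(minus), "-")]),
        "context": np.concatenate([ctx_plus, ctx_minus]),
    })


def audit_contexts(calls: pd.DataFrame, sequences: Mapping[str, str]) -> pd.DataFrame:
    """Re-derive every site's context from the reference; return mismatching rows.

    An empty result certifies that the stored contexts of ``calls`` are
    consistent with the FASTA they claim to describe.
    """
    ref = classify_contexts(sequences).set_index(["chrom", "pos", "strand"])["context"]
    key = pd.MultiIndex.from_frame(calls[["chrom", "pos", "strand"]])
    derived = ref.reindex(key).to_numpy()
    bad = derived != calls["context"].to_numpy()
    return calls.loc[bad]


# ---------------------------------------------------------------------------
# Call tables
# ---------------------------------------------------------------------------

def read_calls(path: str | os.PathLike) -> pd.DataFrame:
    """Read a call-table TSV, validating every row.

    Raises :class:`CallTableError` naming the first offending line for
    malformed rows (bad strand/context, negative counts, mc > total).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise CallTableError(f"{path}: missing columns {missing}")
    df = df[CALL_COLUMNS].copy()
    # line numbers: +2 for header and 1-based counting
    lines = df.index.to_numpy() + 2

    def reject(mask: np.ndarray, why: str) -> None:
        if mask.any():
            raise CallTableError(f"{path}: line {lines[mask][0]}: {why}")

    reject(~df["strand"].isin(["+", "-"]).to_numpy(), "strand must be + or -")
    reject(~df["context"].isin(CONTEXTS).to_numpy(), "context must be CG/CHG/CHH")
    for col in ("pos", "mc_count", "total_count"):
        if not np.issubdtype(df[col].dtype, np.integer):
            coerced = pd.to_numeric(df[col], errors="coerce")
            reject(coerced.isna().to_numpy() | (coerced % 1 != 0).to_numpy(),
                   f"{col} must be an integer")
            df[col] = coerced.astype(np.int64)
    reject((df["pos"] < 1).to_numpy(), "pos must be >= 1 (1-based)")
    reject((df["mc_count"] < 0).to_numpy(), "mc_count must be >= 0")
    reject((df["total_count"] < 0).to_numpy(), "total_count must be >= 0")
    reject((df["mc_count"] > df["total_count"]).to_numpy(),
           "mc_count exceeds total_count")
    df["pos"] = df["pos"] - 1  # to 0-based
    return df


def write_calls(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    out = sites[CALL_COLUMNS].copy()
    out["pos"] = out["pos"] + 1  # to 1-based
    out.to_csv(path, sep="\t", index=False)


def read_methratio(path: str | os.PathLike) -> pd.DataFrame:
    """Adapter for BSMAP/methratio native output.

    methratio reports one row per cytosine with columns
    ``chr pos strand context ratio eff_CT_count C_count CT_count ...`` where
    ``context`` is the 5-mer centred on the cytosine.  This maps C_count ->
    mc_count and CT_count -> total_count and collapses the 5-mer to the
    CG/CHG/CHH class.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    five = df["context"].astype(str)

    def collapse(s: str) -> str:
        if len(s) >= 5:
            if s[3] == "G":
                return "CG"
            if s[4] == "G":
                return "CHG"
            return "CHH"
        return s  # already a class label
    out = pd.DataFrame({
        "chrom": df["chr"],
        "pos": df["pos"].astype(np.int64) - 1,
        "strand": df["strand"],
        "context": five.map(collapse),
        "mc_count": df["C_count"].astype(np.int64),
        "total_count": df["CT_count"].astype(np.int64),
    })
    return out


def pool_replicates(replicates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum mc/total counts across replicate call tables, site by site."""
    cat = pd.concat(replicates, ignore_index=True)
    pooled = (cat.groupby(["chrom", "pos", "strand", "context"], as_index=False,
                          sort=True)[["mc_count", "total_count"]].sum())
    return pooled


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genes: pd.DataFrame, gene_parts: pd.DataFrame, tes: pd.DataFrame,
               gene_path: str | os.PathLike, te_path: str | os.PathLike) -> None:
    """Write gene and TE annotation GFF3 files (1-based inclusive on disk)."""
    with open(gene_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            base = (g.chrom, "stemethyl", "%s", str(g.start + 1), str(g.end),
                    ".", g.strand, ".")
            fh.write("\t".join(base) % "gene" + f"\tID={g.gene_id}\n")
            fh.write("\t".join(base) % "mRNA"
                     + f"\tID={g.gene_id}.1;Parent={g.gene_id}\n")
            parts = gene_parts[gene_parts["gene_id"] == g.gene_id]
            for p in parts.sort_values("start").itertuples():
                fh.write("\t".join((g.chrom, "stemethyl", p.kind,
                                    str(p.start + 1), str(p.end), ".",
                                    g.strand,
                                    "0" if p.kind == "CDS" else ".",
                                    f"Parent={g.gene_id}.1")) + "\n")
    with open(te_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in tes.itertuples():
            fh.write("\t".join((t.chrom, "stemethyl", "repeat_region",
                                str(t.start + 1), str(t.end), ".", t.strand, ".",
                                f"ID={t.te_id};te_class={t.te_class};"
                                f"te_superfamily={t.te_superfamily}")) + "\n")


def read_gene_gff3(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene GFF3 into (genes, gene_parts) DataFrames, 0-based half-open."""
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes, parts = [], []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes["ID"][0]
        genes.append((gene_id, g.seqid, g.start - 1, g.end, g.strand))
        for mrna in db.children(g, featuretype="mRNA"):
            for p in db.children(mrna):
                parts.append((gene_id, p.featuretype, p.start - 1, p.end))
    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                            "strand"])
    parts_df = pd.DataFrame(parts, columns=["gene_id", "kind", "start", "end"])
    return genes_df, parts_df


def read_te_gff3(path: str | os.PathLike) -> pd.DataFrame:
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for t in db.features_of_type("repeat_region"):
        rows.append((t.attributes["ID"][0], t.seqid, t.start - 1, t.end, t.strand,
                     t.attributes.get("te_class", [""])[0],
                     t.attributes.get("te_superfamily", [""])[0]))
    return pd.DataFrame(rows, columns=["te_id", "chrom", "start", "end", "strand",
                                       "te_class", "te_superfamily"])


# ---------------------------------------------------------------------------
# Derived genomic features
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["feature_id", "gene_id", "chrom", "start", "end", "strand",
                   "kind", "te_class", "te_superfamily"]


def derive_features(genes: pd.DataFrame, gene_parts: pd.DataFrame,
                    tes: pd.DataFrame, chrom_sizes: Mapping[str, int],
                    flank: int = 2000) -> pd.DataFrame:
    """Expand annotations into the analysis feature set.

    Adds, per gene: gene_body, a strand-aware promoter (``flank`` bp upstream
    of the TSS), downstream_2kb (``flank`` bp past the TES), exon/intron/UTR
    parts; per TE: the TE span plus its up/downstream ``flank`` regions.
    Introns are the gaps between consecutive exons of the transcript.  All
    derived intervals are clipped to chromosome bounds; empty clips dropped.
    """
    rows: list[tuple] = []

    def add(fid, gid, chrom, start, end, strand, kind, te_class="", te_sf=""):
        size = chrom_sizes[chrom]
        start, end = max(0, start), min(size, end)
        if end > start:
            rows.append((fid, gid, chrom, start, end, strand, kind, te_class, te_sf))

    for g in genes.itertuples():
        gid = g.gene_id
        add(f"{gid}:gene_body", gid, g.chrom, g.start, g.end, g.strand, "gene_body")
        if g.strand == "+":
            add(f"{gid}:promoter", gid, g.chrom, g.start - flank, g.start,
                g.strand, "promoter")
            add(f"{gid}:downstream_2kb", gid, g.chrom, g.end, g.end + flank,
                g.strand, "downstream_2kb")
        else:
            add(f"{gid}:promoter", gid, g.chrom, g.end, g.end + flank,
                g.strand, "promoter")
            add(f"{gid}:downstream_2kb", gid, g.chrom, g.start - flank, g.start,
                g.strand, "downstream_2kb")
        parts = gene_parts[gene_parts["gene_id"] == gid].sort_values("start")
        if ((parts["start"] < g.start) | (parts["end"] > g.end)).any():
            raise ValueError(f"gene {gid}: exon/UTR outside the gene span")
        exons = parts[parts["kind"] == "exon"]
        for i, p in enumerate(parts.itertuples()):
            if p.kind in ("five_prime_UTR", "three_prime_UTR", "exon"):
                add(f"{gid}:{p.kind}:{i}", gid, g.chrom, p.start, p.end,
                    g.strand, p.kind)
        prev_end = None
        for i, e in enumerate(exons.sort_values("start").itertuples()):
            if prev_end is not None and e.start > prev_end:
                add(f"{gid}:intron:{i}", gid, g.chrom, prev_end, e.start,
                    g.strand, "intron")
            prev_end = e.end

    for t in tes.itertuples():
        add(t.te_id, None, t.chrom, t.start, t.end, t.strand, "TE",
            t.te_class, t.te_superfamily)
        add(f"{t.te_id}:upstream_2kb", None, t.chrom, t.start - flank, t.start,
            t.strand, "te_upstream_2kb", t.te_class, t.te_superfamily)
        add(f"{t.te_id}:downstream_2kb", None, t.chrom, t.end, t.end + flank,
            t.strand, "te_downstream_2kb", t.te_class, t.te_superfamily)

    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def overlap_join(sites: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Join cytosine sites onto every feature interval containing them.

    Sites inside overlapping features appear once per feature.  Returns the
    site columns plus the feature columns (feature row suffix ``_feature``
    on name clashes).
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in features.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (s, e, i) for i, s, e in zip(sub.index, sub["start"], sub["end"]))
    site_idx, feat_idx = [], []
    for chrom, sub in sites.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        pos = sub["pos"].to_numpy()
        for i, p in zip(sub.index, pos):
            for iv in tree.at(p):
                site_idx.append(i)
                feat_idx.append(iv.data)
    left = sites.loc[site_idx].reset_index(drop=True)
    right = (features.loc[feat_idx].reset_index(drop=True)
             .drop(columns=["chrom"]))
    right = right.rename(columns={c: f"{c}_feature" for c in right.columns
                                  if c in left.columns})
    return pd.concat([left, right], axis=1)


def write_bed6(intervals: pd.DataFrame, path: str | os.PathLike,
               name: str = "name", score: str = "score") -> None:
    """Export intervals (0-based half-open, BED-native) as BED6."""
    bed = pd.DataFrame({
        "chrom": intervals["chrom"],
        "start": intervals["start"],
        "end": intervals["end"],
        "name": intervals[name] if name in intervals else ".",
        "score": intervals[score] if score in intervals else 0,
        "strand": intervals["strand"] if "strand" in intervals else ".",
    })
    bed.to_csv(path, sep="\t", index=False, header=False)
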