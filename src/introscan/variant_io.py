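"""Standard-format I/O and site filtering.

Reads multi-sample VCFs into a :class:`~introscan.containers.GenotypeMatrix`
and applies the study's site filters: biallelic-SNP restriction, QUAL >= 30,
LD pruning (r^2 <= 0.8 within 5 kb) and the ascertainment filter (>= 3 alt
alleles, >= 1 hom-alt and >= 1 hom-ref sample). All filters are idempotent
and order-stable. Also hosts small readers for population maps, GFF3 gene
annotations, BED intervals and newick trees.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PopulationMap

__all__ = [
    "read_vcf",
    "filter_biallelic_snps",
    "filter_qual",
    "ld_prune",
    "ascertainment_filter",
    "read_population_map",
    "read_gff_genes",
    "read_bed",
    "read_newick_trees",
]

_BASES = frozenset("ACGT")

# cyvcf2 gt_types codes -> alt dosage
_GT_TYPE_TO_DOSAGE = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}


def read_vcf(path, samples: list[str] | None = None) -> GenotypeMatrix:
    """Read a VCF/BCF into a genotype matrix.

    Multi-allelic and non-SNP records are retained but flagged
    (``is_biallelic_snp`` False); dosage is the count of non-reference
    allele copies, computed from GT regardless of phasing. ``samples``
    restricts and orders the columns.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=samples, gts012=False)
    kept = list(vcf.samples)
    if samples is not None:
        missing = set(samples) - set(kept)
        if missing:
            raise KeyError(f"samples not in VCF: {sorted(missing)}")

    contig_lengths: dict[str, int] = {}
    try:
        for name, length in zip(vcf.seqnames, vcf.seqlens):
            contig_lengths[name] = int(length)
    except AttributeError:  # header without contig length lines
        pass

    rows, dosages = [], []
    for i, v in enumerate(vcf):
        if v.gt_types is None or len(v.gt_types) != len(kept):
            raise ValueError(f"record {i + 1} ({v.CHROM}:{v.POS}): missing GT")
        alts = [a for a in v.ALT if a != "<NON_REF>"]
        biallelic = (
            len(alts) == 1
            and len(v.REF) == 1
            and v.REF in _BASES
            and len(alts[0]) == 1
            and alts[0] in _BASES
        )
        rows.append(
            (
                v.CHROM,
                v.POS - 1,  # to 0-based
                v.REF,
                ",".join(alts) if alts else ".",
                np.nan if v.QUAL is None else float(v.QUAL),
                biallelic,
            )
        )
        dosages.append([_GT_TYPE_TO_DOSAGE[t] for t in v.gt_types])

    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "qual", "is_biallelic_snp"]
    )
    dosage = (
        np.asarray(dosages, dtype=float).T
        if dosages
        else np.empty((len(kept), 0))
    )
    gm = GenotypeMatrix(
        samples=kept, sites=sites, dosage=dosage, contig_lengths=contig_lengths
    )
    if samples is not None and kept != list(samples):
        gm = gm.take_samples(list(samples))
    # enforce (chrom, pos) sort order
    order = np.lexsort((gm.sites["pos"].to_numpy(), gm.sites["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(gm.n_sites)):
        gm = gm.take_sites(order)
    return gm


def filter_biallelic_snps(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only sites with exactly one alt allele, both alleles one base."""
    return gm.take_sites(gm.sites["is_biallelic_snp"].to_numpy(dtype=bool))


def filter_qual(gm: GenotypeMatrix, min_qual: float = 30.0) -> GenotypeMatrix:
    """Drop sites with QUAL below ``min_qual`` (missing QUAL counts as 0)."""
    qual = np.nan_to_num(gm.sites["qual"].to_numpy(dtype=float), nan=0.0)
    return gm.take_sites(qual >= min_qual)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise
    complete calls; 0 when fewer than 2 complete pairs or zero variance."""
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix, r2_max: float = 0.8, window_bp: int = 5000
) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning.

    A site is dropped when its genotype correlation r^2 with any
    already-kept site on the same chromosome less than ``window_bp``
    upstream exceeds ``r2_max``. Earlier-position sites win ties, so the
    result is deterministic and idempotent.
    """
    chroms = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    keep = np.zeros(gm.n_sites, dtype=bool)
    kept_idx: list[int] = []
    for j in range(gm.n_sites):
        drop = False
        for k in reversed(kept_idx):
            if chroms[k] != chroms[j] or pos[j] - pos[k] >= window_bp:
                break
            if _pairwise_r2(gm.dosage[:, k], gm.dosage[:, j]) > r2_max:
                drop = True
                break
        if not drop:
            keep[j] = True
            kept_idx.append(j)
    return gm.take_sites(keep)


def ascertainment_filter(
    gm: GenotypeMatrix, min_alt_alleles: int = 3
) -> GenotypeMatrix:
    """Keep sites with >= ``min_alt_alleles`` alt allele copies and at
    least one hom-alt and one hom-ref call (ascertainment-bias criterion
    used before model-based tree inference)."""
    d = gm.dosage
    with np.errstate(invalid="ignore"):
        alt_count = np.nansum(d, axis=0)
        has_hom_alt = (d == 2.0).any(axis=0)
        has_hom_ref = (d == 0.0).any(axis=0)
    return gm.take_sites((alt_count >= min_alt_alleles) & has_hom_alt & has_hom_ref)


def read_population_map(path) -> PopulationMap:
    """Read a TSV of ``sample<TAB>population[<TAB>role]`` (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    if "sample" not in cols:  # headerless file: first row was data
        df = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, header=None
        )
        df.columns = ["sample", "population", "role"][: df.shape[1]]
    else:
        df.columns = cols
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 tab-separated columns")
    assignments = dict(zip(df["sample"], df["population"]))
    roles: dict[str, str] = {}
    if "role" in df.columns:
        for pop, role in zip(df["population"], df["role"]):
            if role:
                roles[pop] = role
    return PopulationMap(assignments=assignments, roles=roles)


def read_gff_genes(path, protein_coding_only: bool = True) -> pd.DataFrame:
    """Read gene features from a GFF3 annotation.

    Returns a DataFrame with ``gene_id, chrom, start, end, strand, biotype``
    where start/end are 0-based half-open (GFF is 1-based inclusive on
    disk). With ``protein_coding_only`` genes are restricted to those whose
    ``gene_biotype``/``biotype`` attribute is ``protein_coding`` (genes
    without a biotype attribute are kept, since minimal annotations omit
    it).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        biotype = (
            feat.attributes.get("gene_biotype", feat.attributes.get("biotype", [""]))
        )[0]
        if protein_coding_only and biotype and biotype != "protein_coding":
            continue
        gene_id = (feat.attributes.get("ID", [feat.id]))[0]
        rows.append((gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand, biotype))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
    )


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file; coordinates are already 0-based half-open."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={0: str, 1: int, 2: int},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    bad = df.index[df["end"] < df["start"]]
    if len(bad):
        raise ValueError(f"{path}: end < start at line {bad[0] + 1}")
    return df


def read_newick_trees(path) -> list:
    """Read newline-delimited newick trees with dendropy (one taxon
    namespace per tree, tip labels preserved verbatim)."""
    import dendropy

    trees = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(
                    dendropy.Tree.get(
                        data=line,
                        schema="newick",
                        preserve_underscores=True,
                    )
                )
            except Exception as exc:
                raise ValueError(f"{path}: malformed newick at line {line_no}: {exc}")
    return trees
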