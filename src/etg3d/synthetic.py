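"""Synthetic toy genomes for exercising the full pairing pipeline.

The generator emulates, at reduced scale, the statistical structure the
method assumes: nested TAD segmentations whose mean domain size grows with
the resolution window and whose boundaries jitter across datasets;
per-cell-type activity matrices in which planted true pairs share a latent
activity factor tuned to a target first canonical correlation; and matching
eQTL-like and capture-Hi-C-like truth sets.  Everything is driven by a
single seeded generator, so fixtures are byte-identical across runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .activity import ENHANCER_MARKS, PROMOTER_MARKS, FeatureTensor
from .hc_score import DEFAULT_WINDOWS, TadEnsemble
from .regions import EnhancerCatalogue, GeneAnnotation, Interval, Peak, PromoterSet

__all__ = [
    "SimConfig",
    "make_genome",
    "make_tad_hierarchy",
    "make_activity",
    "make_truth_sets",
    "make_two_group_pvalues",
    "write_fixture",
]

#: target mean TAD size (bp) per resolution window, coarser levels larger
_TAD_MEAN_SIZE = {5: 183_000, 10: 250_000, 20: 350_000, 50: 525_000}


@dataclass
class SimConfig:
    """Knobs of the toy study; defaults mirror the real design at toy scale.

    k = 44 cell types, windows [5, 10, 20, 50] and 11 Hi-C datasets match
    the full-scale study; the genome itself (2 chromosomes of 10 Mb, 500
    enhancers, 60 promoters) is small enough for second-scale tests while
    leaving room for several dozen TADs per chromosome.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len_bp: int = 10_000_000
    n_enh: int = 500
    n_prom: int = 60
    k: int = 44
    W: tuple[int, ...] = DEFAULT_WINDOWS
    n_datasets: int = 11
    frac_true: float = 0.1
    rho: float = 0.9
    boundary_jitter_bp: int = 20_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_true <= 1.0:
            raise ValueError("frac_true must be in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _template_boundaries(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Shared finest-level boundary template, one array per chromosome."""
    mean = _TAD_MEAN_SIZE[min(cfg.W)] if min(cfg.W) in _TAD_MEAN_SIZE else 183_000
    out = {}
    for chrom in cfg.chroms:
        sizes = rng.gamma(shape=4.0, scale=mean / 4.0, size=cfg.chrom_len_bp // mean + 10)
        sizes = np.maximum(sizes.astype(int), 30_000)
        bounds = np.cumsum(sizes)
        bounds = bounds[bounds < cfg.chrom_len_bp - 30_000]
        out[chrom] = np.concatenate([[0], bounds, [cfg.chrom_len_bp]])
    return out


def make_tad_hierarchy(cfg: SimConfig) -> list[TadEnsemble]:
    """Nested per-dataset TAD segmentations across the resolution windows.

    Within a dataset, the boundaries at a coarser window are an exact
    subset of the finer window's boundaries (a fixed number of internal
    boundaries is removed, so the mean TAD size strictly grows with the
    window).  Across datasets, boundary positions are jittered around a
    shared template, emulating cell-type variation in domain calls.
    """
    rng = cfg.rng()
    template = _template_boundaries(cfg, rng)
    windows = sorted(cfg.W)
    mean_fine = _TAD_MEAN_SIZE.get(windows[0], 183_000)
    ensembles: list[TadEnsemble] = []
    for d in range(cfg.n_datasets):
        dataset_id = f"D{d + 1}"
        per_chrom_bounds: dict[str, dict[int, np.ndarray]] = {}
        for chrom, tmpl in template.items():
            inner = tmpl[1:-1]
            if cfg.boundary_jitter_bp > 0 and inner.size:
                jit = rng.integers(
                    -cfg.boundary_jitter_bp, cfg.boundary_jitter_bp + 1, inner.size
                )
                inner = np.sort(np.clip(inner + jit, 10_000, cfg.chrom_len_bp - 10_000))
                inner = np.unique(inner)
            fine = np.concatenate([[0], inner, [cfg.chrom_len_bp]])
            levels = {windows[0]: fine}
            prev = fine
            for w in windows[1:]:
                target = _TAD_MEAN_SIZE.get(w, mean_fine * w / windows[0])
                n_keep = max(1, int(round(cfg.chrom_len_bp / target)) - 1)
                inner_prev = prev[1:-1]
                n_keep = min(n_keep, inner_prev.size)
                if inner_prev.size > 0 and n_keep == inner_prev.size:
                    n_keep = inner_prev.size - 1  # strict coarsening
                keep = (
                    np.sort(rng.choice(inner_prev.size, size=n_keep, replace=False))
                    if n_keep > 0
                    else np.array([], dtype=int)
                )
                prev = np.concatenate([[0], inner_prev[keep], [cfg.chrom_len_bp]])
                levels[w] = prev
            per_chrom_bounds[chrom] = levels
        for w in windows:
            tads = []
            for chrom in cfg.chroms:
                b = per_chrom_bounds[chrom][w]
                tads.extend(
                    Interval(chrom, int(s), int(e)) for s, e in zip(b[:-1], b[1:])
                )
            ensembles.append(TadEnsemble(dataset_id, w, tads))
    return ensembles


def make_genome(
    cfg: SimConfig,
) -> tuple[EnhancerCatalogue, PromoterSet, list[GeneAnnotation], list[tuple[int, int]]]:
    """Toy enhancer catalogue, promoter set, gene annotation and true pairs.

    Promoter TSSes are spread evenly; enhancers are placed uniformly with
    realistic lengths (mean around 300 bp), deduplicated and sorted.  True
    pairs link each of ``frac_true * n_enh`` enhancers to the nearest
    promoter TSS on its chromosome, so planted pairs are overwhelmingly
    TAD-confined.
    """
    rng = cfg.rng()
    genes: list[GeneAnnotation] = []
    prom_per_chrom = cfg.n_prom // cfg.n_chrom
    g = 0
    for chrom in cfg.chroms:
        spacing = cfg.chrom_len_bp // (prom_per_chrom + 1)
        for j in range(prom_per_chrom):
            tss = spacing * (j + 1) + int(rng.integers(-spacing // 4, spacing // 4))
            strand = "+" if rng.random() < 0.5 else "-"
            exon = Interval(chrom, tss + 200, tss + 400) if strand == "+" else Interval(
                chrom, tss - 400, tss - 200
            )
            genes.append(GeneAnnotation(f"GENE{g + 1}", chrom, tss, strand, (exon,)))
            g += 1
    # enhancers: uniform placement away from promoter windows
    enh: list[Interval] = []
    per_chrom = cfg.n_enh // cfg.n_chrom
    for chrom in cfg.chroms:
        tss_here = np.array([x.tss for x in genes if x.chrom == chrom])
        made = 0
        while made < per_chrom:
            start = int(rng.integers(10_000, cfg.chrom_len_bp - 10_000))
            length = int(np.clip(rng.gamma(3.0, 100.0), 50, 2000))
            mid = start + length // 2
            if tss_here.size and np.min(np.abs(tss_here - mid)) < 5000:
                continue
            enh.append(Interval(chrom, start, start + length))
            made += 1
    enh = sorted(set(enh), key=lambda i: (i.chrom, i.start, i.end))
    # drop overlapping duplicates to keep the catalogue disjoint
    disjoint: list[Interval] = []
    for iv in enh:
        if disjoint and disjoint[-1].chrom == iv.chrom and iv.start < disjoint[-1].end:
            continue
        disjoint.append(iv)
    cat = EnhancerCatalogue(disjoint)
    prom = PromoterSet(
        [
            (Interval(x.chrom, max(0, x.tss - 1500), x.tss + 500) if x.strand == "+"
             else Interval(x.chrom, max(0, x.tss - 500), x.tss + 1500),
             frozenset({x.symbol}))
            for x in genes
        ]
    )
    n_true = int(round(cfg.frac_true * cat.n))
    chosen = rng.choice(cat.n, size=n_true, replace=False)
    prom_mids = np.array([iv.mid for iv, _ in prom.promoters])
    prom_chrom = np.array([iv.chrom for iv, _ in prom.promoters])
    true_pairs = []
    for idx in sorted(chosen):
        e = cat.enhancers[idx]
        cand = np.flatnonzero(prom_chrom == e.chrom)
        j = cand[np.argmin(np.abs(prom_mids[cand] - e.mid))]
        true_pairs.append((idx + 1, int(j) + 1))
    return cat, prom, genes, true_pairs


def make_activity(
    cfg: SimConfig,
    cat: EnhancerCatalogue,
    prom: PromoterSet,
    true_pairs: list[tuple[int, int]],
) -> FeatureTensor:
    """Per-element activity blocks with the planted correlation structure.

    Signals are generated on the log2(x+1) scale as Gaussians around a
    baseline (mean 3, sd 1, floored at 0) and are returned after inverse
    mapping to raw non-negative enrichments, so the log transform and
    normalization are exercised nontrivially downstream.  For each true
    pair, the first DHS column of the enhancer and of the promoter load on
    a shared per-pair latent factor with loading sqrt(rho) each, putting
    the population first canonical correlation at rho; all other columns
    are independent noise.
    """
    rng = cfg.rng()
    k, p, q = cfg.k, len(ENHANCER_MARKS), len(PROMOTER_MARKS)
    X = rng.standard_normal((cat.n, k, p))
    Y = rng.standard_normal((prom.m, k, q))
    load = np.sqrt(cfg.rho)
    noise = np.sqrt(1.0 - cfg.rho)
    # one latent factor per promoter: every enhancer truly paired with it
    # loads on the same factor, so shared-promoter pairs all stay correlated
    factor: dict[int, np.ndarray] = {}
    for enh_id, prom_id in true_pairs:
        if prom_id not in factor:
            factor[prom_id] = rng.standard_normal(k)
            Y[prom_id - 1, :, 0] = load * factor[prom_id] + noise * rng.standard_normal(k)
        X[enh_id - 1, :, 0] = load * factor[prom_id] + noise * rng.standard_normal(k)
    X = np.maximum(3.0 + X, 0.0)
    Y = np.maximum(3.0 + Y, 0.0)
    return FeatureTensor(
        X=np.exp2(X) - 1.0,
        Y=np.exp2(Y) - 1.0,
        enh_ids=np.arange(1, cat.n + 1),
        prom_ids=np.arange(1, prom.m + 1),
        cell_types=[f"CT{c + 1}" for c in range(k)],
    )


def make_truth_sets(
    cfg: SimConfig,
    cat: EnhancerCatalogue,
    prom: PromoterSet,
    true_pairs: list[tuple[int, int]],
) -> tuple[pd.DataFrame, list[tuple[Interval, Interval, float]]]:
    """eQTL-like and capture-Hi-C-like references covering the true pairs.

    One SNP is placed uniformly inside each true enhancer, targeting the
    paired promoter's gene; the cHi-C list carries one interaction per true
    pair with the promoter (+/- 2 kb) as bait and the enhancer (+/- 2 kb)
    as other end.
    """
    rng = cfg.rng()
    rows = []
    chic = []
    for enh_id, prom_id in true_pairs:
        e = cat.enhancers[enh_id - 1]
        piv, syms = prom.promoters[prom_id - 1]
        pos = int(rng.integers(e.start, e.end))
        gene = sorted(syms)[0]
        rows.append((e.chrom, pos, gene))
        bait = Interval(piv.chrom, max(0, piv.start - 2000), piv.end + 2000)
        other = Interval(e.chrom, max(0, e.start - 2000), e.end + 2000)
        chic.append((bait, other, 5.0 + float(rng.random() * 10)))
    eqtl = pd.DataFrame(rows, columns=["chrom", "pos", "gene"])
    return eqtl, chic


def make_two_group_pvalues(
    n: int,
    frac_true: float,
    rng: np.random.Generator,
    informative: bool = True,
    signal_beta: tuple[float, float] = (0.1, 1.0),
) -> pd.DataFrame:
    """A two-groups testing instance with HC-like side information.

    Null p-values are uniform; non-null p-values follow
    Beta(``signal_beta``), concentrated near zero.  The side score lives on
    the HC scale (0 to ~88); when informative, non-nulls sit higher
    (Beta(5,2) vs Beta(2,5) times 88) so the covariate is predictive but
    overlapping, as the HC score is for real pairs.
    """
    z = rng.random(n) < frac_true
    p = rng.random(n)
    p[z] = rng.beta(*signal_beta, size=int(z.sum()))
    if informative:
        x = np.where(z, rng.beta(5, 2, n), rng.beta(2, 5, n)) * 88.0
    else:
        x = rng.beta(2, 5, n) * 88.0
    return pd.DataFrame({"pvalue": p, "side": x, "nonnull": z})


def write_fixture(cfg: SimConfig, outdir: str) -> dict[str, str]:
    """Materialize a complete toy input set in the pipeline's file formats.

    Writes per-cell-type narrowPeak files for H3K27ac and DNase (each
    planted enhancer appears in a random ~70% of cell types; the H3K27ac
    peak extends 200 bp beyond the DNase peak so their base-pair
    intersection recovers the enhancer), a gene table, TAD BEDs with a
    manifest, activity matrices and the truth sets.  Returns a name->path
    map of everything written.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = cfg.rng()
    cat, prom, genes, true_pairs = make_genome(cfg)
    paths: dict[str, str] = {}

    n_cells_peaks = 3
    for ct in range(n_cells_peaks):
        ac_rows, dhs_rows = [], []
        for e in cat.enhancers:
            if rng.random() > 0.7:
                continue
            q_ac = float(rng.uniform(2, 30))
            q_dhs = float(rng.uniform(2, 30))
            ac_rows.append((Interval(e.chrom, max(0, e.start - 200), e.end + 200), q_ac))
            dhs_rows.append((e, q_dhs))
        for kind, rows in (("h3k27ac", ac_rows), ("dhs", dhs_rows)):
            path = os.path.join(outdir, f"{kind}_CT{ct + 1}.narrowPeak")
            with open(path, "w") as fh:
                for iv, qv in rows:
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak\t0\t.\t0\t0\t{qv:.3f}\t-1\n"
                    )
            paths[f"{kind}_CT{ct + 1}"] = path

    paths["genes"] = os.path.join(outdir, "genes.tsv")
    io.write_gene_table(paths["genes"], genes)

    manifest_rows = []
    for ens in make_tad_hierarchy(cfg):
        name = f"tads_{ens.dataset_id}_w{ens.window}.bed"
        io.write_bed(os.path.join(outdir, name), ens.tads)
        manifest_rows.append((ens.dataset_id, ens.window, name))
    paths["tad_manifest"] = os.path.join(outdir, "tad_manifest.tsv")
    pd.DataFrame(manifest_rows, columns=["dataset_id", "window", "path"]).to_csv(
        paths["tad_manifest"], sep="\t", index=False
    )

    tensor = make_activity(cfg, cat, prom, true_pairs)
    for m, mark in enumerate(ENHANCER_MARKS):
        path = os.path.join(outdir, f"enh_{mark}.tsv")
        io.write_activity_matrix(
            path,
            pd.DataFrame(tensor.X[:, :, m], index=tensor.enh_ids, columns=tensor.cell_types),
        )
        paths[f"enh_{mark}"] = path
    for m, mark in enumerate(PROMOTER_MARKS):
        path = os.path.join(outdir, f"prom_{mark}.tsv")
        io.write_activity_matrix(
            path,
            pd.DataFrame(tensor.Y[:, :, m], index=tensor.prom_ids, columns=tensor.cell_types),
        )
        paths[f"prom_{mark}"] = path

    paths["enhancers"] = os.path.join(outdir, "enhancers.bed")
    io.write_bed(paths["enhancers"], cat.enhancers)
    paths["promoters"] = os.path.join(outdir, "promoters.bed")
    io.write_bed(
        paths["promoters"],
        [iv for iv, _ in prom.promoters],
        names=[",".join(sorted(g)) for _, g in prom.promoters],
    )

    eqtl, chic = make_truth_sets(cfg, cat, prom, true_pairs)
    paths["eqtl"] = os.path.join(outdir, "eqtl.tsv")
    eqtl.to_csv(paths["eqtl"], sep="\t", index=False)
    paths["chic"] = os.path.join(outdir, "chic.txt")
    with open(paths["chic"], "w") as fh:
        for bait, other, score in chic:
            fh.write(
                f"{bait.chrom}:{bait.start}-{bait.end}\t"
                f"{other.chrom}:{other.start}-{other.end}\t{score:.2f}\n"
            )
    paths["true_pairs"] = os.path.join(outdir, "true_pairs.tsv")
    pd.DataFrame(true_pairs, columns=["enh_id", "prom_id"]).to_csv(
        paths["true_pairs"], sep="\t", index=False
    )
    return paths
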