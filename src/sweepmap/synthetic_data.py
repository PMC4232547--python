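"""Simulators with full ground truth for every downstream stage.

Three generators are provided:

* an F2 intercross (selfed F1) meiosis simulator with co-segregating "twin"
  marker clusters, genotyping error and missingness — the mapping-population
  branch;
* a structured diversity panel (wild / semi-wild / cultivated) drawn from the
  Balding-Nichols model with a planted low-diversity sweep region — the
  population-genetics branch;
* a neutral infinite-sites coalescent (no recombination) returning
  site-frequency configurations — the Tajima's D calibration harness.

Crossovers follow a Poisson process along the genetic map (Haldane model, no
interference), so for a chromosome of length L cM each gamete carries on
average L/100 crossovers.  Genotypes are coded 0/1/2 = parent-A homozygote /
heterozygote / parent-B homozygote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, make_marker_table

SUBPOPS = ("wild", "semi_wild", "cultivated")


def _check_rate(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a finite value in [0, 1], got {value}")
    return value


@dataclass
class ChromosomeSpec:
    """One simulated chromosome.

    ``intensity_segments`` optionally modulates local crossover intensity:
    a list of ``(start_bp, end_bp, multiplier)`` with multiplier relative to
    the chromosome background (1.0).  The bp -> cM map integrates this
    piecewise-constant intensity and is rescaled so the total genetic length
    equals ``genetic_length_cm`` (a multiplier < 1 plants a recombination
    cold spot, > 1 a hotspot).
    """

    name: str
    genetic_length_cm: float
    physical_length_bp: int
    intensity_segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.genetic_length_cm > 0):
            raise ValueError("genetic_length_cm must be > 0")
        if not (self.physical_length_bp > 0):
            raise ValueError("physical_length_bp must be > 0")
        for start, end, mult in self.intensity_segments:
            if not (0 <= start < end <= self.physical_length_bp) or mult < 0:
                raise ValueError("invalid intensity segment")

    def bp_to_cm(self, bp: np.ndarray) -> np.ndarray:
        """Map physical positions to genetic positions via the intensity map."""
        bp = np.asarray(bp, dtype=np.float64)
        edges = [0.0, float(self.physical_length_bp)]
        for start, end, _ in self.intensity_segments:
            edges.extend([float(start), float(end)])
        edges = np.unique(edges)
        intensity = np.ones(len(edges) - 1)
        for start, end, mult in self.intensity_segments:
            sel = (edges[:-1] >= start) & (edges[1:] <= end)
            intensity[sel] = mult
        seg_cm = intensity * np.diff(edges)
        cum = np.concatenate([[0.0], np.cumsum(seg_cm)])
        total = cum[-1]
        raw = np.interp(bp, edges, cum)
        return raw / total * self.genetic_length_cm


def _as_chrom_spec(spec) -> ChromosomeSpec:
    if isinstance(spec, ChromosomeSpec):
        return spec
    return ChromosomeSpec(*spec)


# Genetic lengths follow the three largest linkage groups of a dense
# cucurbit map (107.4, 112, 88.7 cM); physical lengths chosen so the mean
# recombination rate is ~1.2 cM/Mb.
_DEFAULT_F2_CHROMOSOMES = [
    ("chr1", 107.4, 89_500_000),
    ("chr2", 112.0, 93_300_000),
    ("chr3", 88.7, 73_900_000),
]


@dataclass
class F2SimConfig:
    n_progeny: int = 113
    chromosomes: list = field(default_factory=lambda: list(_DEFAULT_F2_CHROMOSOMES))
    n_markers_per_chrom: int = 200
    twin_cluster_rate: float = 0.2
    genotype_error_rate: float = 0.01
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny < 2:
            raise ValueError("n_progeny must be >= 2")
        if self.n_markers_per_chrom < 2:
            raise ValueError("n_markers_per_chrom must be >= 2")
        self.twin_cluster_rate = _check_rate("twin_cluster_rate", self.twin_cluster_rate)
        self.genotype_error_rate = _check_rate("genotype_error_rate", self.genotype_error_rate)
        self.missing_rate = _check_rate("missing_rate", self.missing_rate)
        self.chromosomes = [_as_chrom_spec(c) for c in self.chromosomes]


@dataclass
class PanelSimConfig:
    n_per_subpop: dict = field(
        default_factory=lambda: {"wild": 22, "semi_wild": 13, "cultivated": 51}
    )
    n_markers: int = 2000
    chromosomes: list = field(default_factory=lambda: [("chr1", 1.0, 10_000_000)])
    fst_per_subpop: dict = field(
        default_factory=lambda: {"wild": 0.20, "semi_wild": 0.25, "cultivated": 0.35}
    )
    ancestral_maf_range: tuple = (0.05, 0.5)
    sweep_region: tuple = ("chr1", 4_000_000, 6_000_000)
    sweep_diversity_factor: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for pop, n in self.n_per_subpop.items():
            if n < 1:
                raise ValueError(f"subpopulation {pop!r} is empty")
        for pop, f in self.fst_per_subpop.items():
            if not (0.0 < f < 1.0):
                raise ValueError(f"fst for {pop!r} must lie in (0, 1), got {f}")
        if not (0.0 < self.sweep_diversity_factor <= 1.0):
            raise ValueError("sweep_diversity_factor must lie in (0, 1]")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo < hi <= 0.5")
        self.chromosomes = [_as_chrom_spec(c) for c in self.chromosomes]
        chrom_names = {c.name for c in self.chromosomes}
        chrom, start, end = self.sweep_region
        spec = {c.name: c for c in self.chromosomes}.get(chrom)
        if spec is None:
            raise ValueError(f"sweep chromosome {chrom!r} not among declared chromosomes")
        if not (0 <= start < end <= spec.physical_length_bp):
            raise ValueError("sweep_region outside its chromosome")


@dataclass
class PanelTruth:
    """Simulator ground truth covering every marker and sample.

    For the F2 branch: true marker order/cM per chromosome, twin-cluster ids,
    per-meiosis crossover locations and the pre-error genotype matrix.  For
    the diversity panel: subpopulation labels, realized per-subpopulation
    allele frequencies and the planted sweep coordinates.
    """

    marker_table: pd.DataFrame
    config: object
    true_cm: pd.Series | None = None
    true_order: dict | None = None
    twin_group: pd.Series | None = None
    crossovers: dict | None = None
    clean_calls: GenotypeMatrix | None = None
    subpop_labels: pd.Series | None = None
    subpop_freqs: pd.DataFrame | None = None
    sweep_region: tuple | None = None

    def write(self, outdir) -> None:
        """Write truth sidecars: marker table TSV and a key=value config echo."""
        import dataclasses
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table = self.marker_table.copy()
        if self.true_cm is not None:
            table["true_cm"] = self.true_cm.reindex(table["marker_id"]).to_numpy()
        if self.twin_group is not None:
            table["twin_group"] = self.twin_group.reindex(table["marker_id"]).to_numpy()
        table.to_csv(outdir / "truth_markers.tsv", sep="\t", index=False)
        if self.subpop_labels is not None:
            self.subpop_labels.rename("subpop").to_csv(
                outdir / "truth_labels.tsv", sep="\t", index_label="sample_id"
            )
        with open(outdir / "truth_config.txt", "w") as fh:
            for f_ in dataclasses.fields(self.config):
                fh.write(f"{f_.name}={getattr(self.config, f_.name)}\n")
            if self.sweep_region is not None:
                fh.write(f"sweep_region={self.sweep_region}\n")


# ---------------------------------------------------------------------------
# F2 intercross
# ---------------------------------------------------------------------------

def _gamete_alleles(
    cm_positions: np.ndarray, length_cm: float, rng
) -> tuple[np.ndarray, int, np.ndarray]:
    """One meiotic product: alleles at the given cM positions plus the
    starting allele and crossover locations that produced them."""
    n_xo = rng.poisson(length_cm / 100.0)
    xo = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    start = int(rng.integers(0, 2))
    parity = np.searchsorted(xo, cm_positions, side="right") % 2
    return (start ^ parity).astype(np.int8), start, xo


def simulate_f2_population(config: F2SimConfig) -> tuple[GenotypeMatrix, PanelTruth]:
    """Simulate an F2 intercross (selfing meioses of one F1) with twins,
    genotyping error and missingness.

    Twin markers share the exact same genetic position (so they co-segregate
    perfectly before error) but sit at distinct bp within 1 kb, mirroring
    co-segregating GBS tags.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_progeny

    all_ids: list[str] = []
    all_chroms: list[str] = []
    all_bp: list[int] = []
    true_cm: dict[str, float] = {}
    twin_group: dict[str, str] = {}
    true_order: dict[str, list[str]] = {}
    crossovers: dict[str, list] = {}
    clean_cols: list[np.ndarray] = []

    for spec in config.chromosomes:
        n_markers = config.n_markers_per_chrom
        n_twin = int(round(config.twin_cluster_rate * n_markers))
        n_unique = n_markers - n_twin
        bp_unique = np.sort(
            rng.choice(np.arange(1, spec.physical_length_bp + 1), size=n_unique, replace=False)
        )
        cm_unique = spec.bp_to_cm(bp_unique)

        # twins duplicate existing markers at zero genetic distance
        twin_of = (
            rng.choice(n_unique, size=n_twin, replace=n_twin > n_unique)
            if n_twin
            else np.empty(0, dtype=int)
        )
        bp_twin = np.minimum(
            bp_unique[twin_of] + rng.integers(1, 1001, size=n_twin), spec.physical_length_bp
        )

        origin = np.concatenate([np.arange(n_unique), twin_of]).astype(int)
        bp_all = np.concatenate([bp_unique, bp_twin])
        order = np.lexsort((origin, bp_all))
        bp_all = bp_all[order]
        origin = origin[order]

        ids = []
        seen: dict[str, int] = {}
        for b in bp_all:
            base = f"{spec.name}_{int(b)}"
            k = seen.get(base, 0)
            seen[base] = k + 1
            ids.append(base if k == 0 else f"{base}.{k}")
        ids = np.asarray(ids, dtype=object)

        # inheritance computed once per unique genetic position
        geno_unique = np.empty((n, n_unique), dtype=np.int8)
        xo_log = []
        for i in range(n):
            a1, s1, xo1 = _gamete_alleles(cm_unique, spec.genetic_length_cm, rng)
            a2, s2, xo2 = _gamete_alleles(cm_unique, spec.genetic_length_cm, rng)
            geno_unique[i] = a1 + a2
            xo_log.append(((s1, xo1), (s2, xo2)))
        crossovers[spec.name] = xo_log

        geno = geno_unique[:, origin]
        clean_cols.append(geno)

        all_ids.extend(ids)
        all_chroms.extend([spec.name] * n_markers)
        all_bp.extend(int(b) for b in bp_all)
        for mid, o in zip(ids, origin):
            true_cm[mid] = float(cm_unique[o])
            twin_group[mid] = f"{spec.name}_tg{o}"
        order_idx = np.lexsort((bp_all, [true_cm[m] for m in ids]))
        true_order[spec.name] = [ids[k] for k in order_idx]

    clean = np.concatenate(clean_cols, axis=1)
    sample_ids = [f"F2_{i:03d}" for i in range(n)]
    clean_matrix = GenotypeMatrix(sample_ids, all_ids, clean.copy())

    calls = clean.copy()
    if config.genotype_error_rate > 0:
        err = rng.random(calls.shape) < config.genotype_error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < config.missing_rate, MISSING, calls).astype(
            np.int8
        )

    table = make_marker_table(all_ids, all_chroms, all_bp)
    matrix = GenotypeMatrix(sample_ids, all_ids, calls)
    truth = PanelTruth(
        marker_table=table,
        config=config,
        true_cm=pd.Series(true_cm),
        true_order=true_order,
        twin_group=pd.Series(twin_group),
        crossovers=crossovers,
        clean_calls=clean_matrix,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Structured diversity panel
# ---------------------------------------------------------------------------

def _sweep_shrink(q: np.ndarray, factor: float) -> np.ndarray:
    """Push frequencies toward the nearest absorbing state so that
    heterozygosity q'(1-q') = factor * q(1-q) exactly."""
    disc = np.sqrt(np.maximum(1.0 - 4.0 * factor * q * (1.0 - q), 0.0))
    return np.where(q >= 0.5, 0.5 + 0.5 * disc, 0.5 - 0.5 * disc)


def simulate_diversity_panel(config: PanelSimConfig) -> tuple[GenotypeMatrix, PanelTruth]:
    """Balding-Nichols structured panel with a planted sweep.

    Per marker an ancestral frequency p is drawn (minor allele uniform on the
    configured range, randomly oriented); each subpopulation's frequency is
    Beta-distributed with mean p and variance F p (1-p).  Inside the sweep
    region the cultivated frequencies are shrunk toward fixation so expected
    heterozygosity is reduced by exactly ``sweep_diversity_factor``.  Diploid
    genotypes are drawn binomially (markers are unlinked).
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_markers

    lengths = np.array([c.physical_length_bp for c in config.chromosomes], dtype=float)
    n_per_chrom = np.floor(m * lengths / lengths.sum()).astype(int)
    n_per_chrom[0] += m - n_per_chrom.sum()

    chroms, bps = [], []
    for spec, k in zip(config.chromosomes, n_per_chrom):
        bp = np.sort(rng.choice(np.arange(1, spec.physical_length_bp + 1), size=k, replace=False))
        chroms.extend([spec.name] * k)
        bps.extend(int(b) for b in bp)
    ids = [f"{c}_{b}" for c, b in zip(chroms, bps)]
    table = make_marker_table(ids, chroms, bps)

    lo, hi = config.ancestral_maf_range
    maf = rng.uniform(lo, hi, size=m)
    p = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)

    sweep_chrom, sweep_start, sweep_end = config.sweep_region
    in_sweep = (
        (np.asarray(chroms) == sweep_chrom)
        & (np.asarray(bps) >= sweep_start)
        & (np.asarray(bps) < sweep_end)
    )

    labels: list[str] = []
    freqs = {}
    blocks = []
    for pop in SUBPOPS:
        n_pop = config.n_per_subpop.get(pop, 0)
        if n_pop == 0:
            continue
        F = config.fst_per_subpop[pop]
        if F < 1e-9:
            q = p.copy()
        else:
            shape = (1.0 - F) / F
            q = rng.beta(np.maximum(p * shape, 1e-12), np.maximum((1.0 - p) * shape, 1e-12))
        if pop == "cultivated" and config.sweep_diversity_factor < 1.0:
            q = np.where(in_sweep, _sweep_shrink(q, config.sweep_diversity_factor), q)
        freqs[pop] = q
        blocks.append(rng.binomial(2, q, size=(n_pop, m)).astype(np.int8))
        labels.extend([pop] * n_pop)

    calls = np.concatenate(blocks, axis=0)
    sample_ids = [f"{pop[:4]}_{i:03d}" for i, pop in enumerate(labels)]
    matrix = GenotypeMatrix(sample_ids, ids, calls)
    truth = PanelTruth(
        marker_table=table,
        config=config,
        subpop_labels=pd.Series(labels, index=sample_ids),
        subpop_freqs=pd.DataFrame(freqs, index=ids),
        sweep_region=config.sweep_region,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Neutral infinite-sites coalescent
# ---------------------------------------------------------------------------

def simulate_neutral_sample(
    n_sequences: int, theta: float, n_replicates: int, seed: int = 0
) -> list[np.ndarray]:
    """Standard neutral infinite-sites coalescent without recombination.

    Coalescence times while k lineages remain are Exponential(k(k-1)/2) in
    coalescent units; mutations fall on branches as a Poisson process of rate
    theta/2 per lineage per unit time.  Each replicate returns the derived
    allele count of every segregating site (so E[S] = theta * sum_{i<n} 1/i).
    """
    if n_sequences < 2:
        raise ValueError("n_sequences must be >= 2")
    if not (theta > 0):
        raise ValueError("theta must be > 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    for _ in range(n_replicates):
        sizes = [1] * n_sequences  # descendant-leaf count per live lineage
        epoch_len: list[float] = []
        epoch_sizes: list[list[int]] = []
        while len(sizes) > 1:
            k = len(sizes)
            epoch_len.append(rng.exponential(2.0 / (k * (k - 1))))
            epoch_sizes.append(list(sizes))
            i, j = rng.choice(k, size=2, replace=False)
            merged = sizes[i] + sizes[j]
            sizes = [s for idx, s in enumerate(sizes) if idx not in (i, j)]
            sizes.append(merged)
        epoch_len_arr = np.asarray(epoch_len)
        ks = np.asarray([len(s) for s in epoch_sizes])
        branch_per_epoch = ks * epoch_len_arr
        total_len = branch_per_epoch.sum()
        n_mut = rng.poisson(theta / 2.0 * total_len)
        counts = []
        if n_mut:
            epoch_choice = rng.choice(len(epoch_len_arr), size=n_mut,
                                      p=branch_per_epoch / total_len)
            for e in epoch_choice:
                lineage = rng.integers(0, ks[e])
                counts.append(epoch_sizes[e][lineage])
        out.append(np.asarray(sorted(counts), dtype=np.int64))
    return out
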