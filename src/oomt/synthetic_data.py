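"""Synthetic paired single-cell methylome + transcriptome data with known truth.

The generator emulates the statistical structure of a joint scRNA-seq /
scBS-seq study of germinal-vesicle oocytes from young vs. aged females:

* a genome tiled by alternating hypermethylated (75-100%), intermediate
  (25-75%) and hypomethylated (0-25%) domains, with log-normal sizes whose
  medians match the oocyte methylome (20.9 kbp hyper, 24.9 kbp hypo);
  unmethylated domains are made CpG-denser than methylated ones, as CpG
  islands are, which places call-weighted global methylation in the 30-45%
  band observed in oocytes;
* sparse per-cell binary CpG calls: each cell covers a random 3.4-29.9%
  of sites, one read per site by default;
* planted age-associated DMRs (aged rate shifted by ``dmr_delta``, losing
  methylation with probability ``dmr_hypo_fraction``);
* maternal and paternal germline DMRs (gDMRs), methylated / unmethylated
  respectively irrespective of age;
* negative-binomial expression with per-cell size factors, planted
  differential-mean (DE) and differential-variability (DV) genes, an SN
  chromatin-state signature, a young-like subgroup of aged cells, and genes
  whose gene-body methylation is an affine function of their own expression
  in the same cell (transcription-coupled methylation).

Every planted effect is recorded in a :class:`GroundTruth` object so
downstream callers can be scored for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .methylome import (
    CellMethylome,
    DOMAIN_COLUMNS,
    make_call_table,
    write_bed,
    write_coverage_file,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "MethylomeLandscape",
    "SyntheticDataset",
    "simulate_domain_landscape",
    "build_landscape",
    "place_true_dmrs",
    "simulate_cell_methylome",
    "simulate_expression",
    "simulate_methylome_dataset",
    "simulate_paired_dataset",
    "write_dataset",
]


class SizingError(ValueError):
    """Genome too short for the requested domain structure."""


@dataclass
class SimulationConfig:
    """All tunable study conditions; defaults mirror the emulated study."""

    seed: int = 0

    # --- cohort sizes ------------------------------------------------------
    n_young_meth: int = 30
    n_aged_meth: int = 32
    n_young_rna: int = 42
    n_aged_rna: int = 45

    # --- genome / methylome ------------------------------------------------
    genome_length: int = 20_000_000
    chrom: str = "chr1"
    cpg_spacing_mean: float = 100.0
    #: class-specific spacing multipliers; unmethylated domains are CpG-denser
    hyper_spacing_mult: float = 1.2
    hypo_spacing_mult: float = 0.7
    inter_spacing_mult: float = 1.0
    hyper_median_bp: float = 20_900.0
    hypo_median_bp: float = 24_900.0
    inter_median_bp: float = 10_000.0
    domain_log_sigma: float = 0.5
    coverage_range: tuple[float, float] = (0.034, 0.299)
    reads_per_site: int = 1
    #: per-cell, per-domain biological noise on the methylation rate
    cell_noise_sd: float = 0.01
    #: global methylation shift of aged cells, percentage points
    aged_shift_pp: float = -1.0
    # non-CpG context: rate proportional to local CpG rate (~2% base),
    # raised in aged cells
    noncpg_spacing_mean: float = 400.0
    noncpg_scale: float = 0.06
    noncpg_aged_factor: float = 1.25

    # --- planted DMRs ------------------------------------------------------
    n_true_dmrs: int = 0
    dmr_delta: float = 0.20
    dmr_hypo_fraction: float = 0.88
    n_maternal_gdmrs: int = 19
    n_paternal_gdmrs: int = 3
    n_secondary_dmrs: int = 2
    n_x_cgi: int = 3

    # --- expression --------------------------------------------------------
    n_genes: int = 2000
    n_de: int = 100
    n_dv: int = 300
    n_signature: int = 100
    n_coupled: int = 20
    n_maternal: int = 50
    de_lfc: float = 1.0
    de_down_fraction: float = 0.536
    nb_dispersion_inflation: float = 3.0
    sn_fold: float = 2.0
    n_sn_young: int = 12
    n_sn_aged: int = 8
    young_like_fraction: float = 16 / 45
    diversity_loss_fraction: float = 0.06
    maternal_trend_lfc: float = 1.0
    coupled_base: float = 0.5
    coupled_slope: float = 0.15
    #: curated marker panels (SN signature, coupled, maternal genes) are
    #: well-expressed by construction; their baseline means are floored here
    marker_min_mean: float = 5.0
    #: deep Smart-seq2-style oocyte libraries: median ~33 counts per gene
    base_mean_log_mu: float = 3.5
    base_mean_log_sigma: float = 1.5
    base_dispersion: float = 0.3
    dispersion_log_sigma: float = 0.3
    sf_log_sigma: float = 0.2
    n_gene_bodies_extra: int = 100

    def __post_init__(self):
        counts = (
            self.n_young_meth, self.n_aged_meth, self.n_young_rna, self.n_aged_rna,
            self.n_true_dmrs, self.n_genes, self.n_de, self.n_dv,
            self.n_signature, self.n_coupled, self.n_maternal,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        lo, hi = self.coverage_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("coverage_range must lie within (0, 1]")
        if not (0 < self.dmr_delta < 1):
            raise ValueError("dmr_delta must be in (0, 1)")
        if not (0 <= self.dmr_hypo_fraction <= 1):
            raise ValueError("dmr_hypo_fraction must be in [0, 1]")
        if self.sn_fold < 2:
            raise ValueError("sn_fold must be >= 2 (the SN signature is defined "
                             "by at least two-fold overexpression)")
        planted = self.n_de + self.n_dv + self.n_signature + self.n_coupled + self.n_maternal
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene sets ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.genome_length < 10 * max(self.hyper_median_bp, self.hypo_median_bp):
            raise SizingError(
                "genome_length must be at least 10x the largest median domain size"
            )
        if self.reads_per_site < 1:
            raise ValueError("reads_per_site must be >= 1")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted simulation truth for recovery scoring."""

    #: columns: name, direction (hypo_in_aged / hyper_in_aged),
    #: young_rate, aged_rate, effective_delta
    dmrs: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: columns: gene, lfc (log2, aged vs young)
    de_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    dv_genes: list = field(default_factory=list)
    #: columns: gene, slope, lfc, domain
    coupled_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    signature_genes: list = field(default_factory=list)
    maternal_genes: list = field(default_factory=list)
    cell_age: dict = field(default_factory=dict)
    cell_state: dict = field(default_factory=dict)
    young_like: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "dmrs": self.dmrs.to_dict(orient="list") if len(self.dmrs) else {},
            "de_genes": self.de_genes.to_dict(orient="list") if len(self.de_genes) else {},
            "dv_genes": list(self.dv_genes),
            "coupled_genes": (
                self.coupled_genes.to_dict(orient="list") if len(self.coupled_genes) else {}
            ),
            "signature_genes": list(self.signature_genes),
            "maternal_genes": list(self.maternal_genes),
            "cell_age": self.cell_age,
            "cell_state": self.cell_state,
            "young_like": list(self.young_like),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Methylome landscape
# ---------------------------------------------------------------------------

@dataclass
class MethylomeLandscape:
    """Domain tiling plus fixed CpG / non-CpG site positions.

    Site positions are generated once per landscape so that every simulated
    cell reports calls at a shared coordinate system (as real cells do).
    """

    domains: pd.DataFrame            # DomainSet (chrom,start,end,class_label,name)
    cpg_pos: np.ndarray              # 1-based site positions, sorted
    cpg_domain: np.ndarray           # site -> domain row index
    noncpg_pos: np.ndarray
    noncpg_domain: np.ndarray
    chrom: str = "chr1"

    @property
    def n_domains(self) -> int:
        return len(self.domains)


_CLASS_CYCLE = ("hyper", "inter", "hypo", "inter")


def simulate_domain_landscape(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Tile the genome with alternating hyper / inter / hypo / inter domains.

    Domain sizes are log-normal with medians matching the oocyte methylome
    (the reported statistic is the median; the distribution shape is a
    modelling choice).  Returns the DomainSet and the per-domain true
    methylation rate: hyper rates drawn uniform [0.75, 1], hypo [0, 0.25],
    intermediate (0.25, 0.75).

    Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    medians = {
        "hyper": config.hyper_median_bp,
        "hypo": config.hypo_median_bp,
        "inter": config.inter_median_bp,
    }
    sizes, labels = [], []
    pos = 0
    i = 0
    while pos < config.genome_length:
        label = _CLASS_CYCLE[i % len(_CLASS_CYCLE)]
        size = int(rng.lognormal(np.log(medians[label]), config.domain_log_sigma))
        size = max(size, 200)
        size = min(size, config.genome_length - pos)
        sizes.append(size)
        labels.append(label)
        pos += size
        i += 1
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.int64)
    ends = starts + np.asarray(sizes, dtype=np.int64)
    labels = np.asarray(labels)
    names = np.array([f"{lab}_{j:05d}" for j, lab in enumerate(labels)])
    domains = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": ends,
            "class_label": labels,
            "name": names,
        }
    )[DOMAIN_COLUMNS]
    if len(domains) < 4:
        raise SizingError("genome too short for the requested domain structure")
    rates = np.empty(len(domains))
    for label, lo, hi in (("hyper", 0.75, 1.0), ("hypo", 0.0, 0.25), ("inter", 0.25, 0.75)):
        mask = labels == label
        rates[mask] = rng.uniform(lo, hi, mask.sum())
    # keep intermediate rates in the open interval
    inter = labels == "inter"
    rates[inter] = np.clip(rates[inter], 0.2500001, 0.7499999)
    return domains, rates


def _place_sites(
    domains: pd.DataFrame,
    spacing: np.ndarray,
    genome_length: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-process site placement with per-domain mean spacing."""
    lengths = (domains["end"] - domains["start"]).to_numpy()
    counts = rng.poisson(lengths / spacing)
    dom_idx = np.repeat(np.arange(len(domains)), counts)
    offsets = rng.random(counts.sum()) * np.repeat(lengths, counts)
    pos0 = np.repeat(domains["start"].to_numpy(), counts) + offsets.astype(np.int64)
    pos = pos0 + 1  # 1-based
    order = np.argsort(pos, kind="mergesort")
    pos, dom_idx = pos[order], dom_idx[order]
    keep = np.concatenate([[True], np.diff(pos) > 0])
    return pos[keep], dom_idx[keep]


def build_landscape(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[MethylomeLandscape, np.ndarray]:
    """Domain tiling plus site placement; returns (landscape, young rates)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    domains, rates = simulate_domain_landscape(config, rng)
    mult = {
        "hyper": config.hyper_spacing_mult,
        "hypo": config.hypo_spacing_mult,
        "inter": config.inter_spacing_mult,
    }
    spacing = config.cpg_spacing_mean * domains["class_label"].map(mult).to_numpy()
    cpg_pos, cpg_dom = _place_sites(domains, spacing, config.genome_length, rng)
    nc_spacing = np.full(len(domains), config.noncpg_spacing_mean)
    nc_pos, nc_dom = _place_sites(domains, nc_spacing, config.genome_length, rng)
    landscape = MethylomeLandscape(
        domains=domains,
        cpg_pos=cpg_pos,
        cpg_domain=cpg_dom,
        noncpg_pos=nc_pos,
        noncpg_domain=nc_dom,
        chrom=config.chrom,
    )
    return landscape, rates


def place_true_dmrs(
    domains: pd.DataFrame,
    young_rates: np.ndarray,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    exclude: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Plant ``n_true_dmrs`` age-associated DMRs on the domain tiling.

    Directions are drawn first (methylation loss in aged with probability
    ``dmr_hypo_fraction``); each DMR is then assigned a domain, sampling
    preferentially among domains where the full ``dmr_delta`` shift is
    realisable (loss of 20 points needs at least 20 points of methylation).
    When the feasible pool is exhausted the shift is clipped to [0, 1] and
    the effective delta recorded.  All other domains are identical between
    the age groups.

    Returns (aged_rates, truth table with columns name, direction,
    young_rate, aged_rate, effective_delta).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_true_dmrs
    if n > len(domains):
        raise SizingError(
            f"n_true_dmrs={n} exceeds the {len(domains)} available domains"
        )
    aged = young_rates.copy()
    if n == 0:
        return aged, pd.DataFrame(
            columns=["name", "direction", "young_rate", "aged_rate", "effective_delta"]
        )
    hypo_dir = rng.random(n) < config.dmr_hypo_fraction
    excluded = set(exclude or [])
    available = np.array(
        [i for i in range(len(domains)) if i not in excluded], dtype=np.int64
    )
    if n > len(available):
        raise SizingError("not enough non-excluded domains for the requested DMRs")
    feas_hypo = available[young_rates[available] >= config.dmr_delta]
    feas_hyper = available[young_rates[available] <= 1 - config.dmr_delta]

    chosen = np.full(n, -1, dtype=np.int64)
    used: set[int] = set()

    def draw(pool: np.ndarray, fallback: np.ndarray) -> int:
        cand = pool[~np.isin(pool, list(used))] if used else pool
        if len(cand) == 0:
            cand = fallback[~np.isin(fallback, list(used))] if used else fallback
        return int(rng.choice(cand))

    for k in range(n):
        pool = feas_hypo if hypo_dir[k] else feas_hyper
        idx = draw(pool, available)
        chosen[k] = idx
        used.add(idx)

    delta = np.where(hypo_dir, -config.dmr_delta, config.dmr_delta)
    new_rates = np.clip(young_rates[chosen] + delta, 0.0, 1.0)
    aged[chosen] = new_rates
    truth = pd.DataFrame(
        {
            "name": domains["name"].to_numpy()[chosen],
            "direction": np.where(hypo_dir, "hypo_in_aged", "hyper_in_aged"),
            "young_rate": young_rates[chosen],
            "aged_rate": new_rates,
            "effective_delta": np.abs(new_rates - young_rates[chosen]),
        }
    )
    return aged, truth


def simulate_cell_methylome(
    landscape: MethylomeLandscape,
    rates: np.ndarray,
    coverage_fraction: float,
    rng: np.random.Generator,
    *,
    cell_noise_sd: float = 0.01,
    shift_pp: float = 0.0,
    overrides: Optional[Sequence[tuple[int, int, float]]] = None,
    reads_per_site: int = 1,
    include_noncpg: bool = True,
    noncpg_scale: float = 0.06,
    noncpg_factor: float = 1.0,
) -> pd.DataFrame:
    """Simulate one cell's CpGCallTable from a landscape and domain rates.

    Each CpG site is covered independently with probability
    ``coverage_fraction``; a covered site carries ``reads_per_site`` binary
    calls, methylated with probability = its domain rate plus a per-cell
    per-domain Gaussian perturbation (sd ``cell_noise_sd``) and a global
    shift of ``shift_pp`` percentage points, clipped to [0, 1].
    ``overrides`` are (start, end, rate) triples (0-based half-open) that
    replace the domain rate inside the interval before noise — the hook used
    to couple gene-body methylation to that cell's expression.
    """
    if not (0 < coverage_fraction <= 1):
        raise ValueError("coverage_fraction must be in (0, 1]")
    noise = rng.normal(0.0, cell_noise_sd, landscape.n_domains) if cell_noise_sd > 0 else 0.0
    site_rate = rates[landscape.cpg_domain].astype(float)
    if overrides:
        pos0 = landscape.cpg_pos - 1
        for start, end, rate in overrides:
            mask = (pos0 >= start) & (pos0 < end)
            site_rate[mask] = rate
    site_rate = site_rate + (noise[landscape.cpg_domain] if cell_noise_sd > 0 else 0.0)
    site_rate = np.clip(site_rate + shift_pp / 100.0, 0.0, 1.0)

    covered = rng.random(len(landscape.cpg_pos)) < coverage_fraction
    idx = np.flatnonzero(covered)
    meth = rng.binomial(reads_per_site, site_rate[idx])
    table = make_call_table(
        landscape.chrom, landscape.cpg_pos[idx], meth, reads_per_site - meth, context="CpG"
    )
    if include_noncpg and len(landscape.noncpg_pos):
        nc_rate = rates[landscape.noncpg_domain].astype(float)
        if overrides:
            pos0 = landscape.noncpg_pos - 1
            for start, end, rate in overrides:
                mask = (pos0 >= start) & (pos0 < end)
                nc_rate[mask] = rate
        nc_rate = np.clip(nc_rate * noncpg_scale * noncpg_factor, 0.0, 1.0)
        nc_cov = rng.random(len(landscape.noncpg_pos)) < coverage_fraction
        nidx = np.flatnonzero(nc_cov)
        nmeth = rng.binomial(reads_per_site, nc_rate[nidx])
        nc_table = make_call_table(
            landscape.chrom,
            landscape.noncpg_pos[nidx],
            nmeth,
            reads_per_site - nmeth,
            context="CHH",
        )
        table = pd.concat([table, nc_table], ignore_index=True)
    return table


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative-binomial draws parameterised by mean mu and dispersion alpha
    (variance mu + alpha * mu^2)."""
    size = 1.0 / np.maximum(alpha, 1e-12)
    p = size / (size + mu)
    return rng.negative_binomial(size, np.clip(p, 1e-12, 1.0))


def simulate_expression(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the genes x cells count matrix with planted structure.

    Returns (counts, annotations, truth).  Annotations columns: cell_id,
    age_group, chromatin_state, young_like, cluster_id.  Clusters follow the
    maturation trajectory aged-NSN (1), aged young-like NSN (2), young NSN
    (3), SN of either age (4); maternal genes get a monotone expression trend
    along it.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_genes = config.n_genes
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    young = [f"y{i:03d}" for i in range(config.n_young_rna)]
    aged = [f"a{i:03d}" for i in range(config.n_aged_rna)]
    cells = np.array(young + aged)
    is_aged = np.array([c.startswith("a") for c in cells])

    # planted gene sets: disjoint slices of a permutation
    perm = rng.permutation(n_genes)
    ofs = 0
    def take(k):
        nonlocal ofs
        out = perm[ofs : ofs + k]
        ofs += k
        return out
    de_idx = take(config.n_de)
    dv_idx = take(config.n_dv)
    sig_idx = take(config.n_signature)
    coup_idx = take(config.n_coupled)
    mat_idx = take(config.n_maternal)

    # cell states
    sn = np.zeros(len(cells), dtype=bool)
    if config.n_sn_young > min(config.n_sn_young, config.n_young_rna):
        raise ValueError("n_sn_young exceeds n_young_rna")
    sn[rng.choice(config.n_young_rna, size=config.n_sn_young, replace=False)] = True
    aged_pos = np.flatnonzero(is_aged)
    sn[rng.choice(aged_pos, size=config.n_sn_aged, replace=False)] = True
    aged_nsn = aged_pos[~sn[aged_pos]]
    n_yl = int(round(config.young_like_fraction * len(aged_pos)))
    yl_pool = aged_pos[sn[aged_pos]]  # SN aged cells are young-like by construction
    young_like = np.zeros(len(cells), dtype=bool)
    young_like[yl_pool] = True
    extra = max(0, n_yl - len(yl_pool))
    if extra > 0 and len(aged_nsn):
        young_like[rng.choice(aged_nsn, size=min(extra, len(aged_nsn)), replace=False)] = True

    cluster = np.full(len(cells), 3, dtype=int)          # young NSN
    cluster[is_aged & ~young_like] = 1                    # aged NSN
    cluster[is_aged & young_like & ~sn] = 2               # aged young-like NSN
    cluster[sn] = 4                                       # SN, either age

    # gene-level parameters
    base_mean = rng.lognormal(config.base_mean_log_mu, config.base_mean_log_sigma, n_genes)
    for marker_idx in (sig_idx, coup_idx, mat_idx):
        if len(marker_idx):
            base_mean[marker_idx] = np.maximum(base_mean[marker_idx], config.marker_min_mean)
    alpha = rng.lognormal(np.log(config.base_dispersion), config.dispersion_log_sigma, n_genes)
    sf = rng.lognormal(0.0, config.sf_log_sigma, len(cells))

    de_sign = np.where(rng.random(config.n_de) < config.de_down_fraction, -1.0, 1.0)
    de_lfc = de_sign * config.de_lfc
    coup_sign = np.where(rng.random(config.n_coupled) < config.de_down_fraction, -1.0, 1.0)
    coup_lfc = coup_sign * config.de_lfc

    log2_shift = np.zeros((n_genes, len(cells)))
    affected = is_aged & ~young_like
    log2_shift[np.ix_(de_idx, np.flatnonzero(affected))] += de_lfc[:, None]
    log2_shift[np.ix_(coup_idx, np.flatnonzero(affected))] += coup_lfc[:, None]
    log2_shift[np.ix_(sig_idx, np.flatnonzero(sn))] += np.log2(config.sn_fold)
    if config.n_maternal:
        trend = (cluster - 2.5) / 1.5  # -1 .. +1 along the trajectory
        log2_shift[mat_idx, :] += config.maternal_trend_lfc * trend[None, :]

    mu = base_mean[:, None] * (2.0 ** log2_shift) * sf[None, :]
    alpha_mat = np.repeat(alpha[:, None], len(cells), axis=1)
    alpha_mat[np.ix_(dv_idx, np.flatnonzero(is_aged))] *= config.nb_dispersion_inflation
    counts = _nb_draw(rng, mu, alpha_mat)

    # transcript-diversity loss: aged (non young-like) cells silence a random
    # subset of genes, emulating reduced transcriptome complexity
    if config.diversity_loss_fraction > 0:
        for c in np.flatnonzero(affected):
            k = rng.poisson(config.diversity_loss_fraction * n_genes)
            if k:
                drop = rng.choice(n_genes, size=min(k, n_genes), replace=False)
                counts[drop, c] = 0

    counts_df = pd.DataFrame(counts, index=genes, columns=cells)
    annotations = pd.DataFrame(
        {
            "cell_id": cells,
            "age_group": np.where(is_aged, "aged", "young"),
            "chromatin_state": np.where(sn, "SN", "NSN"),
            "young_like": young_like,
            "cluster_id": cluster,
        }
    )
    truth = GroundTruth(
        de_genes=pd.DataFrame({"gene": genes[de_idx], "lfc": de_lfc}),
        dv_genes=list(genes[dv_idx]),
        coupled_genes=pd.DataFrame(
            {
                "gene": genes[coup_idx],
                "slope": config.coupled_slope,
                "lfc": coup_lfc,
                "domain": "",
            }
        ),
        signature_genes=list(genes[sig_idx]),
        maternal_genes=list(genes[mat_idx]),
        cell_age={c: ("aged" if a else "young") for c, a in zip(cells, is_aged)},
        cell_state={c: ("SN" if s else "NSN") for c, s in zip(cells, sn)},
        young_like=list(cells[young_like]),
    )
    return counts_df, annotations, truth


# ---------------------------------------------------------------------------
# Dataset orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    landscape: MethylomeLandscape
    young_rates: np.ndarray
    aged_rates: np.ndarray
    counts: Optional[pd.DataFrame]
    annotations: pd.DataFrame
    methylomes: dict                     # cell_id -> CpGCallTable
    gene_bodies: pd.DataFrame
    gdmrs: pd.DataFrame
    x_cgi: pd.DataFrame
    truth: GroundTruth

    @property
    def domains(self) -> pd.DataFrame:
        return self.landscape.domains

    def cells(self, age_group: Optional[str] = None) -> list[str]:
        ann = self.annotations
        sel = ann if age_group is None else ann[ann["age_group"] == age_group]
        return [c for c in sel["cell_id"] if c in self.methylomes]


def _select_special_domains(
    domains: pd.DataFrame, rates: np.ndarray, config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[int], np.ndarray]:
    """Designate gDMR and X-CGI domains, overriding their rates (age-invariant)."""
    labels = domains["class_label"].to_numpy()
    hyper = np.flatnonzero(labels == "hyper")
    hypo = np.flatnonzero(labels == "hypo")
    n_special_hyper = config.n_maternal_gdmrs
    n_special_hypo = config.n_paternal_gdmrs + config.n_secondary_dmrs + config.n_x_cgi
    rates = rates.copy()
    rows, taken = [], []
    if n_special_hyper and len(hyper) >= n_special_hyper:
        mat = rng.choice(hyper, size=n_special_hyper, replace=False)
        rates[mat] = rng.uniform(0.90, 0.98, len(mat))
        for j, d in enumerate(mat):
            rows.append((d, "gdmr_maternal", f"maternal_gdmr_{j:02d}"))
        taken += list(mat)
    if n_special_hypo and len(hypo) >= n_special_hypo:
        sel = rng.choice(hypo, size=n_special_hypo, replace=False)
        rates[sel] = rng.uniform(0.01, 0.06, len(sel))
        k = 0
        for j in range(config.n_paternal_gdmrs):
            rows.append((sel[k], "gdmr_paternal", f"paternal_gdmr_{j:02d}")); k += 1
        for j in range(config.n_secondary_dmrs):
            rows.append((sel[k], "secondary_dmr", f"secondary_dmr_{j:02d}")); k += 1
        for j in range(config.n_x_cgi):
            rows.append((sel[k], "x_cgi", f"x_cgi_{j:02d}")); k += 1
        taken += list(sel)
    special = pd.DataFrame(
        [
            (
                domains["chrom"].iat[d],
                domains["start"].iat[d],
                domains["end"].iat[d],
                label,
                name,
            )
            for d, label, name in rows
        ],
        columns=DOMAIN_COLUMNS,
    )
    return special, taken, rates


def simulate_methylome_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Methylome-only dataset: landscape, planted DMRs, per-cell call tables."""
    return _simulate(config, with_expression=False)


def simulate_paired_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Joint dataset: expression matrix plus methylomes for a cell subset,
    with transcription-coupled gene-body methylation for the coupled genes."""
    return _simulate(config, with_expression=True)


def _simulate(config: SimulationConfig, with_expression: bool) -> SyntheticDataset:
    rng = np.random.default_rng(config.seed)
    landscape, young_rates = build_landscape(config, rng)
    special, special_idx, young_rates = _select_special_domains(
        landscape.domains, young_rates, config, rng
    )
    aged_rates, dmr_truth = place_true_dmrs(
        landscape.domains, young_rates, config, rng, exclude=special_idx
    )

    counts = None
    gene_bodies = pd.DataFrame(columns=DOMAIN_COLUMNS)
    coupled_map: dict[str, tuple[int, float]] = {}
    norm_z = None
    if with_expression:
        counts, annotations, truth = simulate_expression(config, rng)
        if config.n_young_meth > config.n_young_rna or config.n_aged_meth > config.n_aged_rna:
            raise ValueError("paired dataset requires meth cell counts <= RNA cell counts")
        # assign gene bodies: coupled genes plus extras, each on its own
        # hyper domain (oocyte gene bodies are the methylated domains)
        labels = landscape.domains["class_label"].to_numpy()
        hyper_free = [
            i for i in np.flatnonzero(labels == "hyper")
            if i not in set(special_idx) and landscape.domains["name"].iat[i] not in set(dmr_truth["name"])
        ]
        coupled = list(truth.coupled_genes["gene"]) if len(truth.coupled_genes) else []
        if len(hyper_free) < len(coupled):
            raise SizingError(
                f"only {len(hyper_free)} unreserved hyper domains for "
                f"{len(coupled)} coupled gene bodies; enlarge the genome or "
                "reduce n_coupled / gDMR counts"
            )
        n_extra = min(config.n_gene_bodies_extra, max(0, len(hyper_free) - len(coupled)))
        others = [g for g in counts.index if g not in set(coupled)][:n_extra]
        gb_genes = coupled + others
        gb_domains = rng.choice(hyper_free, size=len(gb_genes), replace=False)
        gene_bodies = pd.DataFrame(
            {
                "chrom": landscape.domains["chrom"].to_numpy()[gb_domains],
                "start": landscape.domains["start"].to_numpy()[gb_domains],
                "end": landscape.domains["end"].to_numpy()[gb_domains],
                "class_label": "gene_body",
                "name": gb_genes,
            }
        )[DOMAIN_COLUMNS]
        if coupled:
            truth.coupled_genes["domain"] = landscape.domains["name"].to_numpy()[
                gb_domains[: len(coupled)]
            ]
        # z-scored log expression of coupled genes, for the affine meth link
        if coupled:
            sub = np.log2(counts.loc[coupled].to_numpy() + 1.0)
            mu = sub.mean(axis=1, keepdims=True)
            sd = sub.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            norm_z = (sub - mu) / sd
            for k, g in enumerate(coupled):
                coupled_map[g] = (int(gb_domains[k]), float(config.coupled_slope))
        # methylome subset: random cells from each age group
        young_cells = annotations[annotations["age_group"] == "young"]["cell_id"].to_numpy()
        aged_cells = annotations[annotations["age_group"] == "aged"]["cell_id"].to_numpy()
        meth_cells = list(rng.choice(young_cells, config.n_young_meth, replace=False)) + list(
            rng.choice(aged_cells, config.n_aged_meth, replace=False)
        )
        annotations["has_methylome"] = annotations["cell_id"].isin(meth_cells)
        cell_list = list(annotations["cell_id"])
    else:
        young_ids = [f"y{i:03d}" for i in range(config.n_young_meth)]
        aged_ids = [f"a{i:03d}" for i in range(config.n_aged_meth)]
        meth_cells = young_ids + aged_ids
        annotations = pd.DataFrame(
            {
                "cell_id": meth_cells,
                "age_group": ["young"] * len(young_ids) + ["aged"] * len(aged_ids),
                "chromatin_state": "unassigned",
                "young_like": False,
                "cluster_id": 0,
                "has_methylome": True,
            }
        )
        truth = GroundTruth(
            cell_age={c: ("young" if c.startswith("y") else "aged") for c in meth_cells},
        )
        cell_list = meth_cells

    truth.dmrs = dmr_truth

    # per-cell methylomes
    lo, hi = config.coverage_range
    methylomes = {}
    ann_idx = annotations.set_index("cell_id")
    cell_pos = {c: i for i, c in enumerate(cell_list)}
    for cell in meth_cells:
        age = ann_idx.loc[cell, "age_group"]
        is_aged = age == "aged"
        rates = aged_rates if is_aged else young_rates
        overrides = []
        if coupled_map and norm_z is not None:
            ci = cell_pos[cell]
            for k, (g, (dom, slope)) in enumerate(coupled_map.items()):
                rate = float(
                    np.clip(config.coupled_base + slope * norm_z[k, ci], 0.02, 0.98)
                )
                overrides.append(
                    (
                        int(landscape.domains["start"].iat[dom]),
                        int(landscape.domains["end"].iat[dom]),
                        rate,
                    )
                )
        coverage = rng.uniform(lo, hi)
        methylomes[cell] = simulate_cell_methylome(
            landscape,
            rates,
            coverage,
            rng,
            cell_noise_sd=config.cell_noise_sd,
            shift_pp=config.aged_shift_pp if is_aged else 0.0,
            overrides=overrides or None,
            reads_per_site=config.reads_per_site,
            noncpg_scale=config.noncpg_scale,
            noncpg_factor=config.noncpg_aged_factor if is_aged else 1.0,
        )

    gdmrs = special[special["class_label"].isin(
        ["gdmr_maternal", "gdmr_paternal", "secondary_dmr"]
    )].reset_index(drop=True)
    x_cgi = special[special["class_label"] == "x_cgi"].reset_index(drop=True)
    return SyntheticDataset(
        config=config,
        landscape=landscape,
        young_rates=young_rates,
        aged_rates=aged_rates,
        counts=counts,
        annotations=annotations,
        methylomes=methylomes,
        gene_bodies=gene_bodies,
        gdmrs=gdmrs,
        x_cgi=x_cgi,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Emit the dataset as plain-text files: one coverage file per cell, a
    tab-separated counts matrix, BED interval sets, a samplesheet and the
    ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cov_dir = outdir / "coverage"
    cov_dir.mkdir(exist_ok=True)
    rows = []
    for cell, calls in ds.methylomes.items():
        path = cov_dir / f"{cell}.cov"
        write_coverage_file(calls, path, context="CpG")
        write_coverage_file(calls, cov_dir / f"{cell}.CHH.cov", context="CHH")
        age = ds.truth.cell_age.get(cell, "unknown")
        rows.append((cell, str(path), age, 100.0))
    pd.DataFrame(rows, columns=["cell_id", "path", "age_group", "mapping_efficiency"]).to_csv(
        outdir / "samplesheet.tsv", sep="\t", index=False
    )
    if ds.counts is not None:
        ds.counts.to_csv(outdir / "counts.tsv", sep="\t")
    ds.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    write_bed(ds.domains, outdir / "domains.bed")
    if len(ds.gene_bodies):
        write_bed(ds.gene_bodies, outdir / "gene_bodies.bed")
    if len(ds.gdmrs):
        write_bed(ds.gdmrs, outdir / "gdmrs.bed")
    if len(ds.x_cgi):
        write_bed(ds.x_cgi, outdir / "x_cgi.bed")
    ds.truth.to_json(outdir / "truth.json")
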