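"""Synthetic ChIP-seq experiment generator with a planted truth record.

Emulates the statistical structure the depth-calibration analysis relies
on, at desk scale (default 2 x 5 Mb), so every stage of the pipeline is
testable without any sequencing download:

* a flat sequencing background in all four libraries (IP and input,
  untreated and treated);
* broad enriched domains (LOCK-like, 100-500 kb) and promoter-localized
  enrichment (TSS +/- 2 kb) in the IP libraries only;
* a small set of isolated extreme-coverage artifact bins present with the
  same intensity in IP *and* input — between-library ratios at these bins
  reflect sequencing depth alone;
* an independent sequencing-depth factor per library;
* a uniform multiplicative biological reduction ``r`` of the true signal
  (background + enrichment) in the treated IP, sparing only the artifact
  component — the global mark loss the method is designed to expose.

Fragments are sampled per bin (Poisson or negative binomial counts, left
endpoints uniform within the generating bin, fixed fragment length), and
the generating parameters are returned as a :class:`SimTruth` record for
recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import (
    BinnedCoverage,
    BinGrid,
    FragmentSet,
    GenomeLayout,
    fragment_coverage,
    make_bin_grid,
)
from .rescale import ScalingResult, estimate_scaling_factor

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "SimulationResult",
    "simulate_experiment",
    "simulate_coverage",
    "expected_coverage",
    "evaluate_recovery",
    "recovery_batch",
    "make_ptm_table",
    "LIBRARIES",
]

LIBRARIES = ("ip_untreated", "ip_treated", "input_untreated", "input_treated")


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic two-condition ChIP-seq experiment.

    Defaults describe the study conditions the pipeline targets: a
    desk-scale genome, 150 isolated artifact bins at 100x background,
    broad 5x domains covering roughly half the genome, promoter-localized
    3x enrichment, a treated/untreated IP depth ratio of 1.75 (so the
    true rescaling factor is 1/1.75 ~ 0.571), an input depth ratio of
    1.3, and a uniform biological reduction r = 0.4 of the treated IP
    signal.
    """

    n_sequences: int = 2
    sequence_length: int = 5_000_000
    bin_size: int = 500
    n_artifact_bins: int = 150
    artifact_intensity: float = 100.0  # fold over background, shared by IP and input
    # Milder alignment-artifact continuum below the top bins: real genomes
    # carry thousands of moderately artifactual bins, and the threshold
    # insensitivity of the estimator rests on that continuum.
    n_minor_artifact_bins: int = 1000
    minor_artifact_intensity_range: tuple[float, float] = (3.0, 20.0)
    n_domains: int = 20
    domain_length_range: tuple[int, int] = (100_000, 500_000)
    domain_fold: float = 5.0
    n_promoters: int = 200
    promoter_fold: float = 3.0
    promoter_flank: int = 2000
    background_rate: float = 0.01  # fragment starts per bp per unit depth
    depth_untreated: float = 1.0  # IP library depth factors
    depth_treated: float = 1.75
    input_depth_untreated: float = 1.0
    input_depth_treated: float = 1.3
    reduction: float = 0.4  # r: biological loss factor in the treated IP
    fragment_length: int = 200
    noise: str = "poisson"  # "poisson" | "negative_binomial"
    dispersion: float = 10.0  # NB size parameter (variance = mu + mu^2/dispersion)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "artifact_intensity",
            "domain_fold",
            "promoter_fold",
            "background_rate",
            "depth_untreated",
            "depth_treated",
            "input_depth_untreated",
            "input_depth_treated",
            "dispersion",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.reduction <= 1:
            raise ValueError("reduction r must be in (0, 1]")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        n_bins = self.n_sequences * (-(-self.sequence_length // self.bin_size))
        if self.n_artifact_bins + self.n_minor_artifact_bins > n_bins:
            raise ValueError("more artifact bins than genome bins")
        lo, hi = self.minor_artifact_intensity_range
        if not 1 <= lo <= hi:
            raise ValueError("minor artifact intensity range must satisfy 1 <= lo <= hi")
        if self.n_domains * self.domain_length_range[1] > self.n_sequences * self.sequence_length:
            raise ValueError("domains cannot fit in the genome")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        if "domain_length_range" in d:
            d = {**d, "domain_length_range": tuple(d["domain_length_range"])}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class SimTruth:
    """Planted generating parameters, for recovery evaluation."""

    artifact_bin_indices: np.ndarray  # global grid indices of the top (major) artifact bins
    artifact_intensities: np.ndarray  # per-artifact fold over background
    minor_artifact_bin_indices: np.ndarray
    minor_artifact_intensities: np.ndarray
    domains: list[tuple[str, int, int]]
    genes: pd.DataFrame  # gene_id, sequence, start, end, strand, tss
    depth_untreated: float
    depth_treated: float
    input_depth_untreated: float
    input_depth_treated: float
    reduction: float
    seed: int

    @property
    def true_factor(self) -> float:
        """The rescaling factor the estimator should recover: d_untreated / d_treated."""
        return self.depth_untreated / self.depth_treated

    @property
    def all_artifact_bins(self) -> np.ndarray:
        """Major and minor artifact bins together (depth-only, no biology)."""
        return np.sort(
            np.concatenate([self.artifact_bin_indices, self.minor_artifact_bin_indices])
        )


@dataclass
class SimulationResult:
    config: SimulationConfig
    layout: GenomeLayout
    grid: BinGrid
    fragments: dict[str, FragmentSet]
    truth: SimTruth

    def coverage(self) -> dict[str, BinnedCoverage]:
        return {k: fragment_coverage(v, self.grid) for k, v in self.fragments.items()}


# ---------------------------------------------------------------------------
# Structure placement
# ---------------------------------------------------------------------------


def _make_layout(cfg: SimulationConfig) -> GenomeLayout:
    return GenomeLayout(
        tuple((f"chr{i + 1}", cfg.sequence_length) for i in range(cfg.n_sequences))
    )


def _place_artifacts(
    rng: np.random.Generator,
    grid: BinGrid,
    n: int,
    domains: list[tuple[str, int, int]],
) -> np.ndarray:
    """n isolated full-size bins outside enriched domains.

    Artifact loci must carry *identical* coverage in IP and input (that
    identity is what makes them a depth standard), so they cannot overlap
    enriched domains; a one-bin margin keeps fragment spill from domains
    out of artifact bins and vice versa, and artifact bins are mutually
    non-adjacent (isolated single-bin pile-ups).
    """
    blocked = np.zeros(grid.n_bins, dtype=bool)
    blocked[grid.bin_lengths < grid.bin_size] = True
    for seq, s, e in domains:
        off = grid.offsets[seq]
        b0 = max(0, s // grid.bin_size - 1)
        b1 = min(grid.bins_per_sequence[seq] - 1, (e - 1) // grid.bin_size + 1)
        blocked[off + b0 : off + b1 + 1] = True
    candidates = np.flatnonzero(~blocked)
    rng.shuffle(candidates)
    chosen: list[int] = []
    taken = np.zeros(grid.n_bins, dtype=bool)
    for b in candidates:
        # >= 2 free bins between artifacts: a bin flanked by two pile-ups
        # would itself collect enough spill to rank among the outliers
        if taken[max(0, b - 2) : b + 3].any():
            continue
        chosen.append(int(b))
        taken[b] = True
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise ValueError("could not place the requested number of artifact bins")
    # returned in (random) placement order so callers can split populations
    return np.asarray(chosen, dtype=np.int64)


# Artifact pile-up intensities vary over orders of magnitude in real data;
# per-bin intensities are drawn log-uniformly over this fold-range around
# the configured scale (geometric center = cfg.artifact_intensity).  The
# between-bin spread dominates counting noise, so ranking bins by observed
# coverage ranks them by true intensity (no winner's-curse ratio bias).
ARTIFACT_INTENSITY_SPREAD = 3.0


def _sample_intensities(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    s = ARTIFACT_INTENSITY_SPREAD
    return scale * np.exp(rng.uniform(-np.log(s), np.log(s), size=n))


def _place_domains(
    rng: np.random.Generator, layout: GenomeLayout, cfg: SimulationConfig
) -> list[tuple[str, int, int]]:
    """Non-overlapping broad domains; lengths uniform in the configured range.

    Domains are dealt round-robin to sequences, then positioned by
    stick-breaking the free space into random gaps.
    """
    lo, hi = cfg.domain_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_domains)
    per_seq: dict[str, list[int]] = {name: [] for name, _ in layout.sequences}
    names = layout.names
    for i, L in enumerate(lengths):
        per_seq[names[i % len(names)]].append(int(L))
    domains: list[tuple[str, int, int]] = []
    for name, seqlen in layout.sequences:
        ls = per_seq[name]
        if not ls:
            continue
        if sum(ls) > seqlen:
            raise ValueError(f"domains do not fit on {name}")
        order = rng.permutation(len(ls))
        ls = [ls[i] for i in order]
        free = seqlen - sum(ls)
        gaps = rng.dirichlet(np.ones(len(ls) + 1)) * free
        pos = 0.0
        for g, L in zip(gaps, ls):
            start = int(pos + g)
            domains.append((name, start, start + L))
            pos = start + L
    return sorted(domains, key=lambda d: (names.index(d[0]), d[1]))


def _place_genes(
    rng: np.random.Generator,
    layout: GenomeLayout,
    grid: BinGrid,
    artifact_bins: np.ndarray,  # all artifact bins, major and minor
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Genes with TSSs whose promoter windows avoid artifact bins.

    Artifact loci are alignment pathologies, not annotated promoters, so
    gene placement steers clear of them (a window overlapping an artifact
    bin would be dominated by artifact signal, not promoter biology).
    """
    flank = cfg.promoter_flank
    art_set = set(int(i) for i in artifact_bins)
    rows = []
    names = layout.names
    tries = 0
    while len(rows) < cfg.n_promoters:
        tries += 1
        if tries > 100 * cfg.n_promoters:
            raise RuntimeError("could not place promoters away from artifact bins")
        seq = names[int(rng.integers(0, len(names)))]
        seqlen = layout.lengths[seq]
        tss = int(rng.integers(flank, seqlen - flank))
        b0 = grid.bin_index(seq, tss - flank)
        b1 = grid.bin_index(seq, tss + flank - 1)
        if any(b in art_set for b in range(b0, b1 + 1)):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(5_000, 20_001))
        if strand == "+":
            start, end = tss, min(tss + glen, seqlen)
        else:
            start, end = max(0, tss - glen), tss
        rows.append(
            {
                "gene_id": f"gene{len(rows) + 1}",
                "sequence": seq,
                "start": start,
                "end": end,
                "strand": strand,
                "tss": tss,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expected per-bin fragment-start rates
# ---------------------------------------------------------------------------


def _add_interval(arr: np.ndarray, grid: BinGrid, seq: str, s: int, e: int, add: float) -> None:
    """Add ``add`` (rate per bp) to bins overlapping [s, e), weighted by overlap fraction."""
    B = grid.bin_size
    off = grid.offsets[seq]
    seqlen = grid.layout.lengths[seq]
    s, e = max(0, s), min(e, seqlen)
    if e <= s:
        return
    b0, b1 = s // B, (e - 1) // B
    idx = np.arange(b0, b1 + 1)
    bin_starts = idx * B
    bin_ends = np.minimum(bin_starts + B, seqlen)
    overlap = np.minimum(bin_ends, e) - np.maximum(bin_starts, s)
    arr[off + idx] += add * overlap / (bin_ends - bin_starts)


def _rate_tracks(
    cfg: SimulationConfig,
    grid: BinGrid,
    artifact_bins: np.ndarray,  # combined major + minor
    artifact_intensities: np.ndarray,  # matching per-bin intensities
    domains: list[tuple[str, int, int]],
    genes: pd.DataFrame,
) -> dict[str, np.ndarray]:
    """Per-bin fragment-start rates (starts per bp) for the four libraries."""
    bg = cfg.background_rate
    signal = np.full(grid.n_bins, bg)  # true mark signal: background + enrichment
    for seq, s, e in domains:
        _add_interval(signal, grid, seq, s, e, bg * (cfg.domain_fold - 1))
    for g in genes.itertuples(index=False):
        _add_interval(
            signal,
            grid,
            g.sequence,
            g.tss - cfg.promoter_flank,
            g.tss + cfg.promoter_flank,
            bg * (cfg.promoter_fold - 1),
        )
    # Artifact bins carry pure mis-alignment pile-up, identical in IP and
    # input apart from depth: the artifact rate *replaces* the local rate
    # (it is not mark enrichment and is not touched by the reduction r).
    is_art = np.zeros(grid.n_bins, dtype=bool)
    is_art[artifact_bins] = True
    art_rate = np.zeros(grid.n_bins)
    art_rate[artifact_bins] = bg * artifact_intensities
    flat = np.full(grid.n_bins, bg)
    r = cfg.reduction
    return {
        "ip_untreated": cfg.depth_untreated * np.where(is_art, art_rate, signal),
        "ip_treated": cfg.depth_treated * np.where(is_art, art_rate, r * signal),
        "input_untreated": cfg.input_depth_untreated * np.where(is_art, art_rate, flat),
        "input_treated": cfg.input_depth_treated * np.where(is_art, art_rate, flat),
    }


@dataclass
class _Structure:
    rng: np.random.Generator
    layout: GenomeLayout
    grid: BinGrid
    domains: list[tuple[str, int, int]]
    major_bins: np.ndarray
    major_intensities: np.ndarray
    minor_bins: np.ndarray
    minor_intensities: np.ndarray
    genes: pd.DataFrame
    rates: dict[str, np.ndarray]


def _structure(cfg: SimulationConfig) -> _Structure:
    """Seeded placement of domains, artifact bins, genes and library rates."""
    rng = np.random.default_rng(cfg.seed)
    layout = _make_layout(cfg)
    grid = make_bin_grid(layout, cfg.bin_size)
    domains = _place_domains(rng, layout, cfg)
    placed = _place_artifacts(
        rng, grid, cfg.n_artifact_bins + cfg.n_minor_artifact_bins, domains
    )
    major = np.sort(placed[: cfg.n_artifact_bins])
    minor = np.sort(placed[cfg.n_artifact_bins :])
    major_int = _sample_intensities(rng, cfg.n_artifact_bins, cfg.artifact_intensity)
    lo, hi = cfg.minor_artifact_intensity_range
    minor_int = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_minor_artifact_bins))
    genes = _place_genes(rng, layout, grid, placed, cfg)
    all_bins = np.concatenate([major, minor])
    all_int = np.concatenate([major_int, minor_int])
    rates = _rate_tracks(cfg, grid, all_bins, all_int, domains, genes)
    return _Structure(rng, layout, grid, domains, major, major_int, minor, minor_int, genes, rates)


# ---------------------------------------------------------------------------
# Fragment sampling
# ---------------------------------------------------------------------------


def _sample_library(
    rng: np.random.Generator, cfg: SimulationConfig, grid: BinGrid, rate: np.ndarray
) -> FragmentSet:
    """Per-bin fragment counts (Poisson or NB), spans centred in the bin.

    A fragment attributed to a bin has its midpoint uniform within the
    bin and extends fragment_length/2 each way (clipped at sequence
    ends), so pile-ups spread symmetrically into flanking bins the way
    paired-end fragment coverage does around a focal locus.
    """
    L = cfg.fragment_length
    by = {}
    for seq, seqlen in grid.layout.sequences:
        sl = grid.sequence_slice(seq)
        lens = grid.bin_lengths[sl]
        lam = rate[sl] * lens
        if cfg.noise == "poisson":
            counts = rng.poisson(lam)
        else:
            n = cfg.dispersion
            p = n / (n + lam)
            counts = np.where(lam > 0, rng.negative_binomial(n, np.where(lam > 0, p, 1.0)), 0)
        bin_starts = np.arange(len(lam), dtype=np.int64) * grid.bin_size
        centers = np.repeat(bin_starts, counts) + rng.integers(0, np.repeat(lens, counts))
        starts = np.maximum(centers - L // 2, 0)
        ends = np.minimum(centers - L // 2 + L, seqlen)
        by[seq] = (starts, ends)
    return FragmentSet(by)


def simulate_experiment(
    config: SimulationConfig, noise_seed: int | None = None
) -> SimulationResult:
    """Generate the four fragment libraries and the planted-truth record.

    Fully reproducible from ``config.seed``: structure placement
    (artifact bins, domains, genes) and fragment sampling consume a single
    seeded generator in a fixed order.  ``noise_seed``, if given, draws
    the fragment counts from an independent stream while keeping the
    structure fixed — independent sequencing replicates of one genome.
    """
    st = _structure(config)
    rng = st.rng if noise_seed is None else np.random.default_rng(noise_seed)
    fragments = {lib: _sample_library(rng, config, st.grid, st.rates[lib]) for lib in LIBRARIES}
    truth = SimTruth(
        artifact_bin_indices=st.major_bins,
        artifact_intensities=st.major_intensities,
        minor_artifact_bin_indices=st.minor_bins,
        minor_artifact_intensities=st.minor_intensities,
        domains=st.domains,
        genes=st.genes,
        depth_untreated=config.depth_untreated,
        depth_treated=config.depth_treated,
        input_depth_untreated=config.input_depth_untreated,
        input_depth_treated=config.input_depth_treated,
        reduction=config.reduction,
        seed=config.seed,
    )
    return SimulationResult(config, st.layout, st.grid, fragments, truth)


def simulate_coverage(config: SimulationConfig) -> tuple[dict[str, BinnedCoverage], SimTruth]:
    """Convenience: simulate and bin all four libraries."""
    res = simulate_experiment(config)
    return res.coverage(), res.truth


def expected_coverage(config: SimulationConfig, library: str) -> BinnedCoverage:
    """Exact expected mean per-base depth per bin under the generating process.

    With fragment counts at per-bp rate rho (constant within a bin) and
    fixed fragment length L <= bin size B, a fragment whose midpoint is
    uniform in the bin keeps ``L - L^2/(4B)`` expected bases in its own
    bin and leaks ``L^2/(8B)`` to each neighbour, so expected fragment
    bases per bin are ``rho * B * (L - L^2/(4B))`` in-bin plus
    ``rho * L^2/8`` from each existing neighbour (bases past a sequence
    end are clipped away and lost).  This is the noise-free law of the
    generator that Monte-Carlo coverage converges to.
    """
    if library not in LIBRARIES:
        raise KeyError(f"unknown library {library!r}; expected one of {LIBRARIES}")
    L, B = config.fragment_length, config.bin_size
    if L > B:
        raise ValueError("closed-form expectation requires fragment_length <= bin_size")
    st = _structure(config)
    layout, grid = st.layout, st.grid
    rate = st.rates[library]
    values = np.zeros(grid.n_bins)
    for seq, seqlen in layout.sequences:
        sl = grid.sequence_slice(seq)
        rho = rate[sl]
        lens = grid.bin_lengths[sl]
        if lens[-1] < L:
            raise ValueError("terminal bin shorter than fragment length; expectation not closed-form")
        # discrete-uniform midpoint u in {0..B-1}; span [c-h, c-h+L), h = L//2
        h = L // 2
        l_left = h * (h + 1) / (2.0 * lens)  # expected bases before the bin, per fragment
        l_right = (L - h) * (L - h - 1) / (2.0 * lens)  # expected bases after the bin
        in_bin = L - l_left - l_right
        n_frag = rho * lens  # expected fragments per bin
        bases = n_frag * in_bin
        bases[1:] += (n_frag * l_right)[:-1]
        bases[:-1] += (n_frag * l_left)[1:]  # bases past a sequence end are lost
        values[sl] = bases / lens
    total = float((values * grid.bin_lengths).sum())
    return BinnedCoverage(grid, values, total)


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------


def evaluate_recovery(truth: SimTruth, result: ScalingResult) -> dict:
    """Signed relative error of the estimated factor against the planted depth ratio."""
    true = truth.true_factor
    return {
        "true_factor": true,
        "estimated_factor": result.factor,
        "relative_error": (result.factor - true) / true,
    }


def recovery_batch(
    config: SimulationConfig, seeds: Iterable[int], k: int = 150
) -> pd.DataFrame:
    """Run the estimator over many seeded simulations of one scenario.

    Returns one row per seed (true/estimated factor, signed relative
    error); summary statistics (mean/max absolute error) are one
    aggregation away.
    """
    rows = []
    for seed in seeds:
        cfg = SimulationConfig(**{**asdict(config), "seed": int(seed)})
        res = simulate_experiment(cfg)
        cov = res.coverage()
        est = estimate_scaling_factor(cov["ip_treated"], cov["ip_untreated"], k=k)
        rec = evaluate_recovery(res.truth, est)
        rows.append({"seed": int(seed), **rec})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Planted PTM tables
# ---------------------------------------------------------------------------

# Baseline H3 modification-state compositions (fractions of each site's
# peptide pool) loosely shaped on naive mouse ES cells.
_PTM_BASELINE: dict[str, dict[str, float]] = {
    "H3K4": {"me0": 0.55, "me1": 0.25, "me2": 0.10, "me3": 0.05, "ac": 0.05},
    "H3K9": {"me0": 0.25, "me1": 0.25, "me2": 0.30, "me3": 0.15, "ac": 0.05},
    "H3K27": {"me0": 0.15, "me1": 0.20, "me2": 0.35, "me3": 0.25, "ac": 0.05},
    "H3K36": {"me0": 0.40, "me1": 0.20, "me2": 0.25, "me3": 0.15},
}


def make_ptm_table(
    seed: int = 0,
    n_replicates: int = 3,
    h3k9me2_untreated: float = 0.30,
    h3k9me2_treated: float = 0.115,
    sigma: float = 0.01,
) -> pd.DataFrame:
    """Planted replicate PTM table with an H3K9me2 loss in the treated condition.

    The treated composition moves H3K9me2 from ``h3k9me2_untreated`` to
    ``h3k9me2_treated`` (defaults: 0.30 -> 0.115, a ~2.6-fold reduction)
    and credits the difference to unmodified H3K9; all other sites are
    unchanged between conditions.  Gaussian noise (sd ``sigma``) is added
    per entry and each (site, condition, replicate) block renormalized to
    sum to 1.
    """
    rng = np.random.default_rng(seed)
    comps = {"untreated": _PTM_BASELINE, "treated": {k: dict(v) for k, v in _PTM_BASELINE.items()}}
    delta = h3k9me2_untreated - h3k9me2_treated
    comps["treated"]["H3K9"]["me2"] = h3k9me2_treated
    comps["treated"]["H3K9"]["me0"] = _PTM_BASELINE["H3K9"]["me0"] + delta
    rows = []
    for cond in ("untreated", "treated"):
        for rep in range(1, n_replicates + 1):
            for site, states in comps[cond].items():
                vals = np.array(list(states.values()))
                noisy = np.clip(vals + rng.normal(0, sigma, size=len(vals)), 1e-6, None)
                noisy /= noisy.sum()
                for state, v in zip(states, noisy):
                    rows.append(
                        {
                            "site": site,
                            "state": state,
                            "condition": cond,
                            "replicate": rep,
                            "abundance": float(v),
                        }
                    )
    return pd.DataFrame(rows)
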