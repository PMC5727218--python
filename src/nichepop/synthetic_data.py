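"""Synthetic landscapes, occurrences, genotypes and alignments with ground truth.

Every generator is a pure function of its configuration and seed, and emits
the ground-truth objects (true suitability surface, true population labels,
true haplotype assignment) alongside the observable data, so every downstream
stage of the pipeline can be tested for parameter recovery without any
external data.

Generators
----------
* :func:`gen_env_layers` — spatially autocorrelated standardized raster
  layers (white noise smoothed with a Gaussian kernel), plus a shifted
  "scenario" stack emulating a past/future climate projection.
* :func:`gen_occurrences` — presence points sampled with probability
  proportional to a logistic function of a known linear+quadratic niche.
* :func:`gen_genotypes` — island-model diploid SNP genotypes with
  Balding–Nichols subpopulation frequencies at a target Fst, optional
  isolation by distance via distance-dependent admixture, planted F1
  hybrids, and missing-at-random calls.
* :func:`gen_alignment` — an aligned sequence set with planted SNP columns
  and one contiguous indel, partitioned into a known set of haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from nichepop.geo_core import EnvGrid, GridLayer, OccurrenceSet
from nichepop.popgen import GenotypeMatrix

__all__ = [
    "SimConfig",
    "gen_env_layers",
    "gen_occurrences",
    "gen_genotypes",
    "gen_alignment",
    "Alignment",
]


@dataclass
class SimConfig:
    """All knobs of the synthetic study system.

    The defaults emulate the shape of a Mediterranean crop-wild-relative
    survey at desk scale: a modest raster window with bioclim-like layers,
    a few hundred presence points per taxon, an island model of a handful of
    populations with moderate differentiation, and a short aligned marker
    region with a few substitutions and one multi-base indel.
    """

    seed: int = 0
    # landscape
    grid_rows: int = 40
    grid_cols: int = 40
    n_layers: int = 3
    autocorr_range: float = 4.0  # Gaussian kernel sigma, in cells
    scenario_shift: float = 1.0  # additive shift (in sd units) for scenario stack
    xllcorner: float = 10.0
    yllcorner: float = 30.0
    cellsize: float = 0.05
    # occurrences
    niche_coefficients: tuple[float, ...] = (2.0, -1.0, 0.0)
    n_occurrences: int = 200
    # genotypes
    n_populations: int = 2
    n_individuals: int = 50  # per population
    n_loci: int = 1000
    target_fst: float = 0.2
    ibd_strength: float = 0.0
    missing_fraction: float = 0.0
    n_hybrids: int = 0
    n_diagnostic_loci: int = 0
    pop_spread_km: float = 80.0  # sd of individual scatter around its population center
    pop_distance_km: float = 500.0  # spacing between neighbouring population centers
    # alignment
    n_sequences: int = 50
    seq_length: int = 300
    n_snp_sites: int = 5
    indel_length: int = 6
    n_haplotypes: int = 7

    def __post_init__(self) -> None:
        for name in (
            "grid_rows",
            "grid_cols",
            "n_layers",
            "n_occurrences",
            "n_populations",
            "n_individuals",
            "n_loci",
            "n_sequences",
            "seq_length",
            "indel_length",
        ):
            if getattr(self, name) < 0 or (name != "n_occurrences" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.target_fst < 1.0):
            raise ValueError("target_fst must lie strictly inside (0, 1)")
        if self.ibd_strength < 0:
            raise ValueError("ibd_strength must be >= 0")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.n_haplotypes > self.n_snp_sites + 2:
            raise ValueError(
                "n_haplotypes cannot exceed n_snp_sites + 2 (stepwise construction)"
            )


# ---------------------------------------------------------------------------
# Environmental layers
# ---------------------------------------------------------------------------


def gen_env_layers(config: SimConfig) -> tuple[EnvGrid, EnvGrid]:
    """Generate a current and a scenario stack of autocorrelated layers.

    Each layer is white noise convolved with a Gaussian kernel of sigma
    ``autocorr_range`` cells, then standardized to mean 0, sd 1 over the
    (unmasked) grid.  The scenario stack is the same fields shifted by
    ``scenario_shift`` standard deviations — a deliberately simple stand-in
    for a past/future climate projection that preserves spatial structure
    while moving every cell's environment.

    Returns ``(current, scenario)``.
    """
    if config.grid_rows < 2 or config.grid_cols < 2:
        raise ValueError("degenerate grid: both dimensions must be >= 2")
    rng = np.random.default_rng(config.seed)
    mask = np.zeros((config.grid_rows, config.grid_cols), dtype=bool)

    def make(values: np.ndarray) -> GridLayer:
        return GridLayer(
            values, mask.copy(), config.xllcorner, config.yllcorner, config.cellsize
        )

    current: dict[str, GridLayer] = {}
    scenario: dict[str, GridLayer] = {}
    for i in range(config.n_layers):
        noise = rng.standard_normal((config.grid_rows, config.grid_cols))
        smooth = gaussian_filter(noise, sigma=config.autocorr_range, mode="reflect")
        smooth = (smooth - smooth.mean()) / smooth.std()
        name = f"BIO{i + 1}"
        current[name] = make(smooth)
        scenario[name] = make(smooth + config.scenario_shift)
    return EnvGrid(current), EnvGrid(scenario)


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------


def _feature_expand(layer_matrix: np.ndarray) -> np.ndarray:
    """Linear + quadratic expansion, matching the niche model's feature set."""
    return np.column_stack([layer_matrix, layer_matrix**2])


def gen_occurrences(
    env: EnvGrid,
    true_coefficients: np.ndarray,
    n: int,
    seed: int,
    taxon: str = "taxon",
) -> tuple[OccurrenceSet, np.ndarray]:
    """Sample presence points from a known parametric niche.

    Cell selection probability is proportional to the logistic of the
    linear+quadratic feature score ``eta = f(x) . beta``; sampling is with
    replacement (a cell can host several points; points are jittered
    uniformly inside their cell so that exact-duplicate coordinates do not
    occur by construction).

    ``true_coefficients`` has length n_layers (linear only) or 2*n_layers
    (linear then quadratic).  Returns the occurrence set together with the
    true per-cell suitability surface (full grid, NaN on masked cells),
    normalized to sum to 1 over unmasked cells.
    """
    rng = np.random.default_rng(seed)
    X = env.layer_matrix()
    n_layers = X.shape[1]
    beta = np.asarray(true_coefficients, dtype=float)
    if beta.size == n_layers:
        beta = np.concatenate([beta, np.zeros(n_layers)])
    if beta.size != 2 * n_layers:
        raise ValueError(
            f"coefficient vector length {beta.size} does not match the feature "
            f"expansion ({n_layers} or {2 * n_layers})"
        )
    if n > env.n_unmasked:
        raise ValueError(f"requested {n} occurrences but only {env.n_unmasked} land cells")

    eta = _feature_expand(X) @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    p = p / p.sum()
    truth = np.full((env.n_rows, env.n_cols), np.nan)
    rows, cols = env.unmasked_indices()
    truth[rows, cols] = p

    idx = rng.choice(p.size, size=n, replace=True, p=p)
    lon_c, lat_c = env.cell_center(rows[idx], cols[idx])
    jitter = (rng.random((n, 2)) - 0.5) * env.cellsize * 0.98
    points = list(zip(lon_c + jitter[:, 0], lat_c + jitter[:, 1]))
    return OccurrenceSet(taxon, points), truth


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def gen_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, dict]:
    """Island-model diploid SNP genotypes with known structure.

    Per locus, an ancestral allele frequency ``p`` is drawn uniformly from
    (0.1, 0.9) and each population's frequency from the Balding–Nichols
    Beta(p(1-F)/F, (1-p)(1-F)/F) distribution with F = ``target_fst``.
    Individuals are scattered around their population's center
    (``pop_spread_km``); with ``ibd_strength`` > 0 each individual's
    genotype is drawn from a distance-weighted mixture of the population
    frequencies, so genetic similarity decays smoothly with geographic
    distance.  ``n_hybrids`` extra individuals are planted as F1s between
    populations 0 and 1 (one gamete from each parental frequency set);
    ``n_diagnostic_loci`` extra loci are fixed for alternate alleles in
    populations 0 and 1.  A ``missing_fraction`` of calls is set missing
    completely at random.

    Returns ``(genotypes, truth)`` where ``truth`` records the population
    labels, per-population allele frequencies and hybrid ids.
    """
    rng = np.random.default_rng(config.seed)
    n_pop = config.n_populations
    n_ind = config.n_individuals
    n_loci = config.n_loci

    # Balding–Nichols population frequencies
    p_anc = rng.uniform(0.1, 0.9, size=n_loci)
    F = config.target_fst
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    pop_freq = rng.beta(a, b, size=(n_pop, n_loci))

    if config.n_diagnostic_loci:
        diag = np.full((n_pop, config.n_diagnostic_loci), 0.5)
        diag[0, :] = 1.0
        if n_pop > 1:
            diag[1, :] = 0.0
        pop_freq = np.concatenate([pop_freq, diag], axis=1)
    n_loci_total = pop_freq.shape[1]

    # population centers on a line, individuals scattered around them
    deg_per_km = 1.0 / 111.0
    centers = np.column_stack(
        [
            config.xllcorner + np.arange(n_pop) * config.pop_distance_km * deg_per_km,
            np.full(n_pop, config.yllcorner + 5.0),
        ]
    )
    labels = np.repeat(np.arange(n_pop), n_ind)
    coords = centers[labels] + rng.normal(
        scale=config.pop_spread_km * deg_per_km, size=(labels.size, 2)
    )

    # per-individual frequency: own population, optionally admixed by distance
    if config.ibd_strength > 0:
        d_km = np.sqrt(((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)) / deg_per_km
        w = np.exp(-d_km / (config.pop_distance_km / 2.0))
        w /= w.sum(axis=1, keepdims=True)
        s = min(1.0, config.ibd_strength)
        ind_freq = (1.0 - s) * pop_freq[labels] + s * (w @ pop_freq)
    else:
        ind_freq = pop_freq[labels]

    geno = rng.binomial(2, ind_freq).astype(float)

    ids = [f"pop{k}_ind{i % n_ind}" for i, k in enumerate(labels)]
    groups = [f"pop{k}" for k in labels]

    hybrid_ids: list[str] = []
    if config.n_hybrids and n_pop >= 2:
        g1 = rng.binomial(1, pop_freq[0], size=(config.n_hybrids, n_loci_total))
        g2 = rng.binomial(1, pop_freq[1], size=(config.n_hybrids, n_loci_total))
        hyb = (g1 + g2).astype(float)
        geno = np.vstack([geno, hyb])
        mid = 0.5 * (centers[0] + centers[1])
        coords = np.vstack(
            [coords, mid + rng.normal(scale=config.pop_spread_km * deg_per_km,
                                      size=(config.n_hybrids, 2))]
        )
        hybrid_ids = [f"hybrid_{i}" for i in range(config.n_hybrids)]
        ids += hybrid_ids
        groups += ["hybrid"] * config.n_hybrids

    if config.missing_fraction > 0:
        miss = rng.random(geno.shape) < config.missing_fraction
        geno[miss] = np.nan

    locus_ids = [f"snp{j}" for j in range(n_loci)] + [
        f"diag{j}" for j in range(n_loci_total - n_loci)
    ]
    gm = GenotypeMatrix(
        dosages=geno,
        individual_ids=ids,
        locus_ids=locus_ids,
        groups=groups,
        coords=coords,
    )
    truth = {
        "population_labels": labels,
        "population_frequencies": pop_freq,
        "ancestral_frequencies": p_anc,
        "hybrid_ids": hybrid_ids,
        "centers": centers,
    }
    return gm, truth


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class Alignment:
    """Equal-length aligned sequences over {A, C, G, T, N, -}."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len({len(s) for s in self.seqs} | (set() if self.seqs else {0})) > 1:
            raise ValueError("ragged alignment: sequences differ in length")

    def __len__(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0


def gen_alignment(config: SimConfig) -> tuple[Alignment, dict]:
    """Aligned sequences with planted SNPs and one contiguous indel.

    A random reference of ``seq_length`` is generated; ``n_snp_sites``
    substitution sites and one indel of ``indel_length`` (coded as a gap run
    in the carrying sequences) define ``n_haplotypes`` haplotypes built as a
    stepwise mutation chain: haplotype *h* carries the first *h* planted
    changes.  Sequence counts per haplotype are as even as possible, so
    every planted character is observed in >= 2 states.

    Returns ``(alignment, truth)`` where truth maps each sequence id to its
    haplotype index and records the planted site positions.
    """
    rng = np.random.default_rng(config.seed)
    n_char = config.n_snp_sites + 1
    if config.n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    if config.seq_length < config.n_snp_sites * 3 + config.indel_length + 2:
        raise ValueError(
            f"seq_length={config.seq_length} too small to host {config.n_snp_sites} "
            f"SNPs plus a {config.indel_length}-bp indel"
        )

    ref = rng.choice(_BASES, size=config.seq_length)
    # place the indel first, then SNP sites outside it, all well separated
    indel_start = int(rng.integers(0, config.seq_length - config.indel_length + 1))
    indel_cols = set(range(indel_start, indel_start + config.indel_length))
    candidates = [i for i in range(config.seq_length) if i not in indel_cols]
    snp_pos = sorted(rng.choice(candidates, size=config.n_snp_sites, replace=False))
    snp_alt = []
    for pos in snp_pos:
        alts = [b for b in "ACGT" if b != ref[pos]]
        snp_alt.append(alts[int(rng.integers(3))])

    # stepwise chain: haplotype h carries planted changes 0..h-1
    n_hap = config.n_haplotypes
    # SNPs are characters 0..n_snp-1, the indel is the last character
    changes = rng.permutation(n_char).tolist()
    hap_states = []
    for h in range(n_hap):
        carried = set(changes[:h])
        hap_states.append(carried)

    counts = np.full(n_hap, config.n_sequences // n_hap)
    counts[: config.n_sequences % n_hap] += 1
    assignment = np.repeat(np.arange(n_hap), counts)
    rng.shuffle(assignment)

    ids, seqs = [], []
    truth_assign = {}
    for i, h in enumerate(assignment):
        seq = ref.copy()
        for c in hap_states[h]:
            if c < config.n_snp_sites:
                seq[snp_pos[c]] = snp_alt[c]
            else:
                seq[list(indel_cols)] = "-"
        sid = f"seq{i}"
        ids.append(sid)
        seqs.append("".join(seq))
        truth_assign[sid] = int(h)

    truth = {
        "haplotype_of": truth_assign,
        "n_haplotypes": int(len(set(assignment))),
        "haplotype_counts": {int(h): int(c) for h, c in zip(*np.unique(assignment,
                                                                       return_counts=True))},
        "snp_positions": snp_pos,
        "indel_span": (indel_start, indel_start + config.indel_length),
    }
    return Alignment(ids, seqs), truth
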