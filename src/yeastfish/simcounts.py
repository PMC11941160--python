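"""Per-cell mRNA count simulator.

Generates long-form count tables with the statistical structure observed in
single-molecule FISH studies of unsynchronised budding yeast: phase-dependent
mean expression, overdispersed ("bursty") counts, latent-Gaussian coupling
between paralogue pairs, deletion strains with compensatory upregulation of
the remaining paralogue, and binomial mother/bud allocation of transcripts.

Count model
-----------
A bursty gene with per-cell mean ``mu`` and dispersion ``burst_size`` ``b``
draws ``N ~ Poisson(mu / s)`` transcriptional bursts of geometric size
(support >= 1) with mean ``s = (b + 1) / 2``; the per-cell count is the sum
of the burst sizes.  This compound distribution has mean ``mu`` and Fano
factor exactly ``b``; ``b = 1`` collapses to Poisson, which is also the
constitutive mode.  Pair coupling is a Gaussian copula applied to the
exact compound-count quantiles, so marginals are preserved exactly and
the attainable count correlation reaches the comonotone bound.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from yeastfish.exceptions import ConfigurationError
from yeastfish.phases import BUDDED_PHASES, MOTHER_PHASES, PHASES, mother_label

COUNT_COLUMNS = [
    "cell_id",
    "experiment_id",
    "strain_id",
    "phase",
    "compartment",
    "gene_id",
    "count",
]

#: bud allocation probability used when a strain specifies none for a gene
DEFAULT_BUD_TRANSPORT = 0.25
#: residual (diffusive) bud allocation when She2p-dependent transport is off
PASSIVE_BUD_TRANSPORT = 0.10


@dataclass(frozen=True)
class GeneModel:
    """Expression model for one gene.

    Parameters
    ----------
    gene_id : str
    mode : {"bursty", "constitutive"}
    mu_by_phase : float or mapping phase -> mean transcripts per cell
        A scalar means the same mean in every phase.  Keys may be any of the
        nine phase labels; a whole cell uses its mother-side label.
    burst_size : float
        Fano factor of the count distribution (>= 1).  Ignored in
        constitutive mode (where counts are Poisson).
    half_life_min : float, optional
        mRNA half-life in minutes.  Metadata only; no decay is simulated.
    """

    gene_id: str
    mode: str = "bursty"
    mu_by_phase: float | Mapping[str, float] = 1.0
    burst_size: float = 3.0
    half_life_min: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("bursty", "constitutive"):
            raise ConfigurationError(f"unknown expression mode {self.mode!r}")
        if self.burst_size < 1:
            raise ConfigurationError("burst_size must be >= 1")
        mus = (
            [self.mu_by_phase]
            if np.isscalar(self.mu_by_phase)
            else list(self.mu_by_phase.values())
        )
        if any(m < 0 for m in mus):
            raise ConfigurationError("phase means must be >= 0")
        if not np.isscalar(self.mu_by_phase):
            for ph in self.mu_by_phase:
                if ph not in PHASES:
                    raise ConfigurationError(f"unknown phase {ph!r} in mu_by_phase")

    def mu(self, phase: str) -> float:
        """Mean transcripts per cell in ``phase`` (mother-side label)."""
        if np.isscalar(self.mu_by_phase):
            return float(self.mu_by_phase)
        key = mother_label(phase)
        return float(self.mu_by_phase.get(key, 0.0))


@dataclass(frozen=True)
class PairCoupling:
    """Latent-Gaussian coupling between two genes.

    ``rho_latent`` is the correlation of the shared Gaussian copula;
    0 means independence.  ``achieved_pearson``/``max_attainable`` are
    filled in by :func:`calibrate_rho`.
    """

    gene_a: str
    gene_b: str
    rho_latent: float
    achieved_pearson: float | None = None
    max_attainable: float | None = None
    attainable: bool = True

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_latent <= 1.0:
            raise ConfigurationError("rho_latent must lie in [-1, 1]")


@dataclass(frozen=True)
class StrainSpec:
    """A strain: deletions, compensatory scaling and bud-transport behaviour.

    ``compensation_factor`` multiplies a gene's phase means before sampling;
    values may be scalars or phase -> factor mappings.  ``bud_transport``
    gives the probability that a transcript of a budded cell sits in the
    bud.  ``she2_active=False`` caps all bud transport at the passive
    (diffusion-only) level, emulating a she2Δ background.
    """

    strain_id: str
    deleted_genes: frozenset[str] = frozenset()
    compensation_factor: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=dict
    )
    bud_transport: Mapping[str, float] = field(default_factory=dict)
    she2_active: bool = True

    def mu_scale(self, gene_id: str, phase: str) -> float:
        fac = self.compensation_factor.get(gene_id, 1.0)
        if isinstance(fac, Mapping):
            fac = fac.get(mother_label(phase), 1.0)
        if fac < 0:
            raise ConfigurationError("compensation factors must be >= 0")
        return float(fac)

    def bud_probability(self, gene_id: str) -> float:
        p = float(self.bud_transport.get(gene_id, DEFAULT_BUD_TRANSPORT))
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError("bud_transport must lie in [0, 1]")
        if not self.she2_active:
            p = min(p, PASSIVE_BUD_TRANSPORT)
        return p


WT = StrainSpec(strain_id="WT")


@dataclass(frozen=True)
class PhaseOccupancy:
    """Probabilities of the nine segmented-object phase labels.

    The mother-side entries (G1, S, G2, Early-M, Late-M), renormalised,
    give the phase distribution of whole-cell sampling units; the ``*-Bud``
    entries describe the extra bud objects the image simulator emits.
    """

    probabilities: Mapping[str, float]

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        for ph in probs:
            if ph not in PHASES:
                raise ConfigurationError(f"unknown phase {ph!r}")
        vals = np.array([probs.get(ph, 0.0) for ph in PHASES])
        if (vals < 0).any():
            raise ConfigurationError("occupancy probabilities must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ConfigurationError("occupancy probabilities must sum to 1")

    def unit_probabilities(self) -> dict[str, float]:
        """Phase distribution of whole-cell units (mother-side labels)."""
        w = {ph: self.probabilities.get(ph, 0.0) for ph in MOTHER_PHASES}
        total = sum(w.values())
        if total <= 0:
            raise ConfigurationError("occupancy has no mass on mother phases")
        return {ph: v / total for ph, v in w.items()}


#: asynchronous-culture default; G1 deliberately overrepresented and S
#: underrepresented, the assignment bias expected for segmented yeast images
DEFAULT_OCCUPANCY = PhaseOccupancy(
    {
        "G1": 0.30,
        "S": 0.08,
        "G2": 0.14,
        "Early-M": 0.07,
        "Late-M": 0.07,
        "S-Bud": 0.08,
        "G2-Bud": 0.14,
        "Early-M-Bud": 0.06,
        "Late-M-Bud": 0.06,
    }
)


def _stream(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic child RNG stream for (seed, keys...)."""
    parts = [int(seed) & 0x7FFFFFFF]
    parts += [zlib.crc32(k.encode()) & 0x7FFFFFFF for k in keys]
    return np.random.default_rng(parts)


def _latent_uniforms(
    genes: Sequence[GeneModel],
    couplings: Sequence[PairCoupling],
    n_cells: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-gene copula uniforms with the requested pairwise correlations."""
    names = [g.gene_id for g in genes]
    index = {n: i for i, n in enumerate(names)}
    corr = np.eye(len(names))
    for c in couplings:
        for n in (c.gene_a, c.gene_b):
            if n not in index:
                raise ConfigurationError(f"coupled gene {n!r} not in gene list")
        i, j = index[c.gene_a], index[c.gene_b]
        corr[i, j] = corr[j, i] = c.rho_latent
    try:
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("coupling matrix is not positive definite") from exc
    z = rng.standard_normal((n_cells, len(names))) @ chol.T
    u = stats.norm.cdf(z)
    return {n: u[:, index[n]] for n in names}


def _polya_aeppli_cdf(lam: float, s: float, tail: float = 1e-12) -> np.ndarray:
    """CDF table of the compound Poisson(lam) x geometric(mean s, >=1) count.

    Panjer recursion for a Poisson primary distribution:
    P(0) = exp(-lam); P(x) = (lam / x) * sum_g g * f_G(g) * P(x - g).
    The table stops once the tail mass drops below ``tail``.
    """
    if lam <= 0:
        return np.array([1.0])
    p = 1.0 / s
    pmf = [np.exp(-lam)]
    total = pmf[0]
    # geometric severity pmf f_G(g) = p (1-p)^(g-1)
    x = 0
    while total < 1.0 - tail and x < 100_000:
        x += 1
        g = np.arange(1, x + 1)
        f_g = p * (1.0 - p) ** (g - 1)
        val = (lam / x) * float(np.dot(g * f_g, np.asarray(pmf[::-1])))
        pmf.append(val)
        total += val
    return np.cumsum(pmf)


def _counts_from_uniforms(
    gene: GeneModel,
    u: np.ndarray,
    mu: np.ndarray,
) -> np.ndarray:
    """Map copula uniforms to counts, preserving the marginal exactly.

    Bursty genes use the exact compound-distribution quantile function
    (one CDF table per distinct phase mean), so both the marginal and the
    copula dependence act on total counts.
    """
    u = np.clip(u, 1e-12, 1 - 1e-12)
    mu = np.maximum(mu, 0.0)
    if gene.mode == "constitutive" or gene.burst_size <= 1.0:
        return stats.poisson.ppf(u, mu).astype(np.int64)
    s = (gene.burst_size + 1.0) / 2.0
    counts = np.zeros(u.shape, dtype=np.int64)
    for m in np.unique(mu):
        mask = mu == m
        cdf = _polya_aeppli_cdf(m / s, s)
        counts[mask] = np.searchsorted(cdf, u[mask], side="left")
    return counts


def simulate_counts(
    genes: Sequence[GeneModel],
    couplings: Sequence[PairCoupling] = (),
    strain: StrainSpec = WT,
    occupancy: PhaseOccupancy = DEFAULT_OCCUPANCY,
    n_cells: int = 1000,
    seed: int = 0,
    experiment_id: str = "sim",
) -> pd.DataFrame:
    """Simulate a long-form per-cell count table.

    Returns one row per cell x gene x compartment: every cell gets a
    ``whole`` row; budded cells (phase S / G2 / Early-M / Late-M) get
    ``mother`` and ``bud`` rows that sum to the whole-cell count.  Deleted
    genes are emitted with count 0.  The table's ``attrs["settings"]``
    records the generator inputs so paired scenarios can be re-simulated.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    gene_ids = {g.gene_id for g in genes}
    # bud_transport may cover genes outside this simulation; deletions and
    # compensation must not, or the scenario silently does nothing
    for name in strain.deleted_genes | set(strain.compensation_factor):
        if name not in gene_ids:
            raise ConfigurationError(f"strain references unknown gene {name!r}")

    rng = _stream(seed, strain.strain_id, experiment_id)
    unit_p = occupancy.unit_probabilities()
    phase_names = list(unit_p)
    phases = rng.choice(phase_names, size=n_cells, p=[unit_p[p] for p in phase_names])
    budded = np.isin(phases, BUDDED_PHASES)
    uniforms = _latent_uniforms(genes, couplings, n_cells, rng)

    frames = []
    cell_ids = np.arange(1, n_cells + 1)
    for gene in genes:
        if gene.gene_id in strain.deleted_genes:
            whole = np.zeros(n_cells, dtype=np.int64)
        else:
            mu = np.array(
                [gene.mu(ph) * strain.mu_scale(gene.gene_id, ph) for ph in phases]
            )
            whole = _counts_from_uniforms(gene, uniforms[gene.gene_id], mu)
        bud_counts = np.zeros(n_cells, dtype=np.int64)
        if budded.any():
            p_bud = strain.bud_probability(gene.gene_id)
            bud_counts[budded] = rng.binomial(whole[budded], p_bud)
        for compartment, values, mask in (
            ("whole", whole, np.ones(n_cells, bool)),
            ("mother", whole - bud_counts, budded),
            ("bud", bud_counts, budded),
        ):
            if not mask.any():
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_ids[mask],
                        "experiment_id": experiment_id,
                        "strain_id": strain.strain_id,
                        "phase": phases[mask],
                        "compartment": compartment,
                        "gene_id": gene.gene_id,
                        "count": values[mask],
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]
    table = table.sort_values(
        ["gene_id", "cell_id", "compartment"], kind="stable"
    ).reset_index(drop=True)
    table.attrs["settings"] = {
        "genes": tuple(genes),
        "couplings": tuple(couplings),
        "occupancy": occupancy,
        "n_cells": n_cells,
        "seed": seed,
        "experiment_id": experiment_id,
        "strain": strain,
    }
    return table


def apply_compensation_scenario(table_wt: pd.DataFrame, strain: StrainSpec) -> pd.DataFrame:
    """Paired deletion-strain table under identical generator settings.

    Re-simulates with the same genes/couplings/occupancy/root seed but the
    given ``strain``; the strain id keys a different child seed stream, so
    the two tables are independent draws (the study compares independently
    grown cultures, not transformed copies).
    """
    settings = table_wt.attrs.get("settings")
    if settings is None:
        raise ConfigurationError(
            "table lacks generator settings; it was not produced by simulate_counts"
        )
    return simulate_counts(
        genes=settings["genes"],
        couplings=settings["couplings"],
        strain=strain,
        occupancy=settings["occupancy"],
        n_cells=settings["n_cells"],
        seed=settings["seed"],
        experiment_id=settings["experiment_id"],
    )


def _pair_pearson(
    rho: float,
    gene_a: GeneModel,
    gene_b: GeneModel,
    mu_a: np.ndarray,
    mu_b: np.ndarray,
    za: np.ndarray,
    zb_raw: np.ndarray,
) -> float:
    """Count-level Pearson at latent correlation ``rho`` (common random numbers)."""
    zb = rho * za + np.sqrt(max(1.0 - rho**2, 0.0)) * zb_raw
    ca = _counts_from_uniforms(gene_a, stats.norm.cdf(za), mu_a)
    cb = _counts_from_uniforms(gene_b, stats.norm.cdf(zb), mu_b)
    if ca.std() == 0 or cb.std() == 0:
        return 0.0
    return float(np.corrcoef(ca, cb)[0, 1])


def calibrate_rho(
    target_pearson: float,
    gene_a: GeneModel,
    gene_b: GeneModel,
    n_pilot: int = 50_000,
    seed: int = 0,
    occupancy: PhaseOccupancy = DEFAULT_OCCUPANCY,
    tol: float = 0.02,
) -> PairCoupling:
    """Find the latent correlation producing a target count-level Pearson.

    The copula attenuates correlation (discreteness + zero inflation), so the
    count Pearson is a nondecreasing function of ``rho_latent``; a bisection
    against pilot simulations with common random numbers inverts it.  If the
    target exceeds the attainable maximum (evaluated at rho = 0.999), the
    returned coupling carries ``attainable=False`` and ``max_attainable``.
    """
    if not -1.0 < target_pearson < 1.0:
        raise ValueError("target_pearson must lie in (-1, 1)")
    if target_pearson == 0.0:
        return PairCoupling(gene_a.gene_id, gene_b.gene_id, 0.0, achieved_pearson=0.0)

    rng = _stream(seed, "calibrate", gene_a.gene_id, gene_b.gene_id)
    unit_p = occupancy.unit_probabilities()
    phases = rng.choice(list(unit_p), size=n_pilot, p=list(unit_p.values()))
    mu_a = np.array([gene_a.mu(ph) for ph in phases])
    mu_b = np.array([gene_b.mu(ph) for ph in phases])
    if mu_a.max() <= 0 or mu_b.max() <= 0:
        raise ConfigurationError("both genes need positive mean in some phase")
    za = rng.standard_normal(n_pilot)
    zb_raw = rng.standard_normal(n_pilot)
    evaluate = lambda rho: _pair_pearson(  # noqa: E731
        rho, gene_a, gene_b, mu_a, mu_b, za, zb_raw
    )

    sign = 1.0 if target_pearson > 0 else -1.0
    goal = abs(target_pearson)
    hi_rho = 0.999
    # magnitude of the count Pearson, nondecreasing in the latent magnitude
    magnitude = lambda r: sign * evaluate(sign * r)  # noqa: E731
    max_attain = magnitude(hi_rho)
    if max_attain < goal:
        return PairCoupling(
            gene_a.gene_id,
            gene_b.gene_id,
            sign * hi_rho,
            achieved_pearson=sign * max_attain,
            max_attainable=sign * max_attain,
            attainable=False,
        )
    lo, hi = 0.0, hi_rho
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        ach = magnitude(mid)
        if abs(ach - goal) < tol * 0.5:
            lo = hi = mid
            break
        if ach < goal:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    r = 0.5 * (lo + hi)
    return PairCoupling(
        gene_a.gene_id,
        gene_b.gene_id,
        float(sign * r),
        achieved_pearson=float(sign * magnitude(r)),
        max_attainable=float(sign * max_attain),
    )


def make_strain(
    strain_id: str,
    deleted: Sequence[str] = (),
    compensation: Mapping[str, float | Mapping[str, float]] | None = None,
    bud_transport: Mapping[str, float] | None = None,
    she2_active: bool = True,
) -> StrainSpec:
    """Convenience constructor for a :class:`StrainSpec`."""
    return StrainSpec(
        strain_id=strain_id,
        deleted_genes=frozenset(deleted),
        compensation_factor=dict(compensation or {}),
        bud_transport=dict(bud_transport or {}),
        she2_active=she2_active,
    )


def read_count_table(path) -> pd.DataFrame:
    """Read a count table CSV written by :func:`write_count_table`."""
    table = pd.read_csv(path)
    missing = set(COUNT_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigurationError(f"count table missing columns: {sorted(missing)}")
    return table


def write_count_table(table: pd.DataFrame, path) -> None:
    table[COUNT_COLUMNS].to_csv(path, index=False)
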