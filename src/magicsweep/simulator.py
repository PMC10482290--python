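"""Forward-time simulation of the 10-generation selection experiment.

The model: 200 diploid individuals whose genome is a set of discrete loci on
5 chromosomes (303, 195, 233, 184, 268 loci by default, one locus per scan
window).  Every locus carries one of 19 allele states, one per founder
accession.  Founders are initialised i.i.d. uniform over the 19 states, so
generation-0 linkage disequilibrium is zero by construction.  Each
generation, a trait value is drawn per individual as Normal(mu, 1) with
mu = allele_effect x (dose of advantageous alleles over all trait loci);
the environmental deviate is redrawn every generation, independent of
genotype history.  Forty parents are picked by the selection regime
(directional = top trait values, stabilising = closest to the generation
mean, random = uniform), randomly paired into 20 disjoint crosses, and each
cross yields 10 offspring.  Gametes recombine with Poisson(2) crossovers per
chromosome placed uniformly on distinct inter-locus gaps.

Effects are strictly additive per allele copy (0/1/2 doses per trait
locus); multiple advantageous alleles at a locus are interchangeable and
share one effect size.  There is no mutation, no dominance and no epistasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import N_FOUNDERS, GenomeLayout, PedigreeTable, ValidationError

REGIMES = ("directional", "stabilising", "random")


@dataclass
class SimConfig:
    """Parameters of one simulated selection experiment."""

    n_individuals: int = 200
    n_selected: int = 40
    n_crosses: int = 20
    progeny_per_cross: int = 10
    n_generations: int = 10
    loci_per_chromosome: tuple[int, ...] = (303, 195, 233, 184, 268)
    recombination_rate: float = 2.0  # mean crossovers per chromosome per meiosis
    n_trait_loci: int = 0
    n_advantageous_alleles: int = 1
    allele_effect: float = 0.0  # trait SD per advantageous allele copy
    regime: str = "directional"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_crosses * self.progeny_per_cross != self.n_individuals:
            raise ValidationError("n_crosses x progeny_per_cross must equal n_individuals")
        if self.n_selected != 2 * self.n_crosses:
            raise ValidationError("n_selected must equal 2 x n_crosses")
        if self.n_trait_loci > sum(self.loci_per_chromosome):
            raise ValidationError("more trait loci than loci")
        if not 1 <= self.n_advantageous_alleles <= N_FOUNDERS:
            raise ValidationError("n_advantageous_alleles must be in 1..19")
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}")
        if self.allele_effect < 0:
            raise ValidationError("allele_effect must be >= 0")
        if self.recombination_rate < 0:
            raise ValidationError("recombination_rate must be >= 0")


@dataclass
class TraitArchitecture:
    """Trait locus placement and the advantageous allele set.

    ``positions`` are ``(chromosome_index, locus_index)`` pairs; the
    advantageous alleles at every trait locus are states ``0..n_adv-1``
    (the founders are exchangeable at initialisation, so which states are
    advantageous is a labelling choice).
    """

    positions: tuple[tuple[int, int], ...]
    n_advantageous_alleles: int = 1
    allele_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.allele_effect < 0:
            raise ValidationError("effect must be >= 0")


@dataclass
class Population:
    """Genotypes of one generation: per chromosome an (n, 2, L) allele array."""

    genotypes: list[np.ndarray]
    ids: np.ndarray  # individual id strings
    family_ids: np.ndarray
    phenotypes: np.ndarray | None = None

    @property
    def size(self) -> int:
        return len(self.ids)


@dataclass
class SimResult:
    """Everything recorded from one simulated experiment."""

    config: SimConfig
    architecture: TraitArchitecture
    pedigree: PedigreeTable
    phenotypes: pd.DataFrame  # individual_id, generation, family_id, trait, selected
    allele_counts: list[list[np.ndarray]]  # [generation][chromosome] -> (19, L)
    final_he: list[np.ndarray]  # per chromosome, per locus
    selection: pd.DataFrame  # generation, S, cumS, R
    h2: float
    mean_inbreeding: np.ndarray | None  # per generation, or None if skipped


def place_trait_loci(n_trait_loci: int,
                     loci_per_chromosome: Sequence[int]) -> tuple[tuple[int, int], ...]:
    """Deterministic trait-locus placement.

    With n <= 5 loci, one locus per distinct chromosome at the central
    index.  With n > 5, loci are apportioned round-robin across the five
    chromosomes and placed at equally spaced interior indices (for m loci
    on a chromosome of L loci, at round((j+1) L/(m+1)), j = 0..m-1, so the
    endpoints are excluded).
    """
    total = sum(loci_per_chromosome)
    if not 1 <= n_trait_loci <= total:
        raise ValidationError("n_trait_loci must be in 1..total loci")
    n_chrom = len(loci_per_chromosome)
    positions: list[tuple[int, int]] = []
    if n_trait_loci <= n_chrom:
        for c in range(n_trait_loci):
            positions.append((c, loci_per_chromosome[c] // 2))
    else:
        base, extra = divmod(n_trait_loci, n_chrom)
        for c, n_loci in enumerate(loci_per_chromosome):
            m = base + (1 if c < extra else 0)
            for j in range(m):
                idx = int(round((j + 1) * n_loci / (m + 1)))
                idx = min(max(idx, 1), n_loci - 2)
                positions.append((c, idx))
    return tuple(positions)


def init_founders(config: SimConfig, rng: np.random.Generator) -> Population:
    """Generation 0: every allele at every locus i.i.d. uniform over the 19
    states; loci mutually independent."""
    genotypes = [
        rng.integers(0, N_FOUNDERS, size=(config.n_individuals, 2, L), dtype=np.int8)
        for L in config.loci_per_chromosome
    ]
    ids = np.array([f"G00_I{i:03d}" for i in range(config.n_individuals)])
    family_ids = np.array(["founder"] * config.n_individuals)
    return Population(genotypes, ids, family_ids)


def advantage_dose(population: Population, architecture: TraitArchitecture) -> np.ndarray:
    """Total advantageous allele copies per individual (0..2 per trait locus)."""
    dose = np.zeros(population.size, dtype=np.int64)
    for c, l in architecture.positions:
        dose += (population.genotypes[c][:, :, l]
                 < architecture.n_advantageous_alleles).sum(axis=1)
    return dose


def assign_phenotypes(population: Population, architecture: TraitArchitecture,
                      rng: np.random.Generator) -> Population:
    """Draw phenotypes ~ Normal(effect x dose, 1), fresh noise each call."""
    mu = architecture.allele_effect * advantage_dose(population, architecture)
    population.phenotypes = mu + rng.standard_normal(population.size)
    return population


def select_parents(phenotypes: np.ndarray, regime: str, n_selected: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Indices of the selected parents; ties broken at random."""
    n = len(phenotypes)
    if n < n_selected:
        raise ValidationError("population smaller than n_selected")
    if regime == "random":
        return rng.choice(n, size=n_selected, replace=False)
    if regime == "directional":
        key = -phenotypes
    elif regime == "stabilising":
        key = np.abs(phenotypes - phenotypes.mean())
    else:
        raise ValidationError(f"unknown regime {regime!r}")
    # lexsort: random tiebreak first, key last (most significant)
    order = np.lexsort((rng.random(n), key))
    return order[:n_selected]


def _make_gametes(parent_geno: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Vectorised meiosis for one chromosome.

    ``parent_geno`` is (n_gametes, 2, L): the two haplotypes of the
    transmitting parent for each gamete.  Crossover count per gamete is
    Poisson(rate) capped at the number of inter-locus gaps; crossover
    positions are distinct gaps chosen uniformly; the starting haplotype is
    random and the copied haplotype alternates at each crossover.
    """
    n, _, L = parent_geno.shape
    n_gaps = L - 1
    ks = np.minimum(rng.poisson(rate, size=n), n_gaps)
    # rank trick: the k smallest of n_gaps iid uniforms mark k distinct gaps
    u = rng.random((n, n_gaps))
    ranks = u.argsort(axis=1, kind="stable").argsort(axis=1, kind="stable")
    cross = ranks < ks[:, None]
    phase = np.empty((n, L), dtype=np.int8)
    phase[:, 0] = rng.integers(0, 2, size=n, dtype=np.int8)
    switches = np.cumsum(cross, axis=1)
    phase[:, 1:] = (phase[:, [0]] + switches) % 2
    return np.take_along_axis(
        parent_geno, phase[:, None, :].astype(np.intp), axis=1)[:, 0, :]


def breed_generation(population: Population, selected_idx: np.ndarray,
                     config: SimConfig, generation: int,
                     rng: np.random.Generator) -> tuple[Population, pd.DataFrame]:
    """Pair the selected parents into disjoint crosses and produce offspring.

    Returns the offspring population and its pedigree rows.
    """
    if len(selected_idx) % 2:
        raise ValidationError("odd number of selected parents")
    perm = rng.permutation(selected_idx)
    pairs = perm.reshape(config.n_crosses, 2)
    sires = np.repeat(pairs[:, 0], config.progeny_per_cross)
    dams = np.repeat(pairs[:, 1], config.progeny_per_cross)
    n_off = len(sires)

    genotypes = []
    for c in range(len(config.loci_per_chromosome)):
        g = population.genotypes[c]
        pat = _make_gametes(g[sires], config.recombination_rate, rng)
        mat = _make_gametes(g[dams], config.recombination_rate, rng)
        genotypes.append(np.stack([pat, mat], axis=1))

    ids = np.array([f"G{generation:02d}_I{i:03d}" for i in range(n_off)])
    family = np.repeat(
        np.array([f"G{generation:02d}_F{j:02d}" for j in range(config.n_crosses)]),
        config.progeny_per_cross)
    pedigree_rows = pd.DataFrame({
        "individual_id": ids,
        "sire_id": population.ids[sires],
        "dam_id": population.ids[dams],
        "generation": generation,
    })
    return Population(genotypes, ids, family), pedigree_rows


def _allele_counts(population: Population) -> list[np.ndarray]:
    """Per chromosome: (19, L) counts of each allele state over 2N genes."""
    out = []
    for g in population.genotypes:
        n, _, L = g.shape
        flat = g.reshape(-1, L).astype(np.int64)
        idx = flat + N_FOUNDERS * np.arange(L)[None, :]
        counts = np.bincount(idx.ravel(), minlength=N_FOUNDERS * L)
        out.append(counts.reshape(L, N_FOUNDERS).T.copy())
    return out


def run_experiment(config: SimConfig, *, compute_inbreeding: bool = True,
                   record_counts: bool = True) -> SimResult:
    """Simulate the whole experiment and summarise it.

    Realised heritability is the zero-intercept regression of the response
    (mean trait at generation t minus the generation-0 mean; the noise is
    mean-zero so the starting mean plays the control role) on the cumulative
    selection differential.
    """
    from . import pedigree as pedigree_mod
    from .quantgen import fit_h2

    rng = np.random.default_rng(config.rng_seed)
    if config.n_trait_loci > 0:
        positions = place_trait_loci(config.n_trait_loci, config.loci_per_chromosome)
    else:
        positions = ()
    arch = TraitArchitecture(positions, config.n_advantageous_alleles,
                             config.allele_effect)

    pop = init_founders(config, rng)
    assign_phenotypes(pop, arch, rng)

    ped_frames = [pd.DataFrame({
        "individual_id": pop.ids,
        "sire_id": pd.Series([None] * pop.size, dtype=object),
        "dam_id": pd.Series([None] * pop.size, dtype=object),
        "generation": 0,
    })]
    pheno_frames = []
    counts = [_allele_counts(pop)] if record_counts else []
    means = [pop.phenotypes.mean()]
    S_series = []

    for gen in range(1, config.n_generations + 1):
        sel = select_parents(pop.phenotypes, config.regime, config.n_selected, rng)
        S = pop.phenotypes[sel].mean() - pop.phenotypes.mean()
        S_series.append(S)
        selected_mask = np.zeros(pop.size, dtype=bool)
        selected_mask[sel] = True
        pheno_frames.append(pd.DataFrame({
            "individual_id": pop.ids, "generation": gen - 1,
            "family_id": pop.family_ids, "trait": pop.phenotypes,
            "selected": selected_mask}))
        pop, ped_rows = breed_generation(pop, sel, config, gen, rng)
        assign_phenotypes(pop, arch, rng)
        ped_frames.append(ped_rows)
        if record_counts:
            counts.append(_allele_counts(pop))
        means.append(pop.phenotypes.mean())

    pheno_frames.append(pd.DataFrame({
        "individual_id": pop.ids, "generation": config.n_generations,
        "family_id": pop.family_ids, "trait": pop.phenotypes,
        "selected": False}))

    final_counts = _allele_counts(pop)
    two_n = 2 * config.n_individuals
    final_he = [1.0 - ((c / two_n) ** 2).sum(axis=0) for c in final_counts]
    if not record_counts:
        counts = [final_counts]

    cumS = np.cumsum(S_series)
    R = np.asarray(means[1:]) - means[0]
    h2 = fit_h2(cumS, R)
    selection = pd.DataFrame({
        "generation": np.arange(1, config.n_generations + 1),
        "S": S_series, "cumS": cumS, "R": R})

    pedigree = PedigreeTable.from_dataframe(pd.concat(ped_frames, ignore_index=True))
    mean_f = None
    if compute_inbreeding:
        report = pedigree_mod.inbreeding_coefficients(pedigree)
        mean_f = report.per_generation["mean_F"].to_numpy()

    return SimResult(
        config=config, architecture=arch, pedigree=pedigree,
        phenotypes=pd.concat(pheno_frames, ignore_index=True),
        allele_counts=counts, final_he=final_he, selection=selection,
        h2=h2, mean_inbreeding=mean_f)
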