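"""Synthetic inputs with known ground truth for every pipeline stage.

Haplotype-frequency fixtures draw window background frequencies from a
Dirichlet centred on the uniform 1/19 spectrum, blend neighbouring windows
to reproduce the strong window-to-window autocorrelation of overlapping
sliding windows, and then inject sweeps by raising a chosen founder subset
to a target total frequency in a contiguous window run.  The default
effective Dirichlet concentration (7.4) is chosen so the background mean
He matches the neutral drift expectation for the experiment,
(18/19)(1 - 1/80)^10 ~ 0.835 after ten generations with 40 parents.

Phenotype fixtures use an infinitesimal model: additive values transmitted
as the mid-parent value plus Mendelian segregation noise of variance Va/2,
environmental noise sized so narrow-sense heritability equals the
requested truth, a shared seasonal shift per generation (which the paired
control population absorbs), and branch counts produced by rounding the
latent value at a floor of zero.

Pedigree fixtures mirror the experimental design (20 disjoint crosses of
10 progeny, census 200) with an optional sibling-enrichment knob that
biases parent choice towards high-value families to mimic the extra
inbreeding caused by directional selection.

SNP fixtures derive their pooled generation-10 frequencies from a supplied
haplotype-frequency table, so SNP and haplotype fixtures share one latent
truth; about half the SNPs are private to a single founder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .io_formats import (FOUNDERS, N_FOUNDERS, GenomeLayout,
                         HaplotypeFrequencyTable, PedigreeTable,
                         PhenotypeTable, SnpTable, ValidationError)


def concentration_for_mean_he(mean_he: float) -> float:
    """Effective Dirichlet concentration giving a target mean background He.

    For a symmetric Dirichlet with total concentration c the expected
    heterozygosity of a draw is 1 - 1/19 - (18/19)/(c + 1); inverting gives
    c = (18/19)/(18/19 - mean_he) - 1.
    """
    top = 1.0 - 1.0 / N_FOUNDERS
    if not 0 < mean_he < top:
        raise ValidationError(f"mean He must lie in (0, {top:.4f})")
    return top / (top - mean_he) - 1.0


#: Background concentration emulating a directionally selected population
#: after ten generations: mean He ~ 0.767, i.e. founder diversity scaled by
#: (1 - F) at a mean inbreeding of ~0.19 (directional selection co-selects
#: siblings, roughly doubling the inbreeding of the random controls).
DIRECTIONAL_CONCENTRATION = concentration_for_mean_he(0.767)

#: Background concentration emulating a random-control population:
#: mean He ~ 0.852, founder diversity scaled by (1 - F) at F ~ 0.10.
CONTROL_CONCENTRATION = concentration_for_mean_he(0.852)


@dataclass(frozen=True)
class SweepInjection:
    """One injected sweep: a founder subset raised to a target total
    frequency across a contiguous run of windows."""

    chrom: str
    first_window: int  # window index within the chromosome
    n_windows: int
    founders: tuple[str, ...]
    target_frequency: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.founders) <= 4:
            raise ValidationError("sweep founder subset size must be 1..4")
        unknown = set(self.founders) - set(FOUNDERS)
        if unknown:
            raise ValidationError(f"unknown founders: {sorted(unknown)}")
        if not 1.0 / N_FOUNDERS < self.target_frequency <= 1.0:
            raise ValidationError("target frequency must lie in (1/19, 1]")
        if self.n_windows < 1 or self.first_window < 0:
            raise ValidationError("invalid window range")


@dataclass
class FixtureSpec:
    """Ground-truth parameters shared by the fixture generators."""

    rng_seed: int = 0
    layout: GenomeLayout = field(default_factory=GenomeLayout.arabidopsis)
    window_size: int = 200_000
    window_step: int = 100_000
    # scan background
    concentration: float = 7.4  # effective (post-smoothing) Dirichlet concentration
    smoothing_span: int = 4     # windows blended together
    sweeps: tuple[SweepInjection, ...] = ()
    # phenotype model
    true_h2: float = 0.1
    baseline_branches: float = 5.0
    phenotypic_sd: float = 2.0
    seasonal_sd: float = 1.0
    batch_sd: float = 1.0  # per-population, per-generation glasshouse batch effect
    plasticity_shift: float = 1.5
    # experiment structure
    n_individuals: int = 200
    n_selected: int = 40
    progeny_per_cross: int = 10
    n_generations: int = 10
    # pedigree
    sibling_enrichment: float = 0.0
    # SNPs
    n_snps: int = 2000

    def __post_init__(self) -> None:
        if self.smoothing_span < 1:
            raise ValidationError("smoothing span must be >= 1")
        if not 0 <= self.true_h2 <= 1:
            raise ValidationError("true h2 must lie in [0, 1]")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        seen: set[tuple[str, int]] = set()
        for sw in self.sweeps:
            windows = {(sw.chrom, w) for w in
                       range(sw.first_window, sw.first_window + sw.n_windows)}
            if windows & seen:
                raise ValidationError("overlapping sweep injections")
            seen |= windows

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


# ---------------------------------------------------------------------------
# Haplotype-frequency fixtures
# ---------------------------------------------------------------------------

def make_scan_fixture(spec: FixtureSpec, population_id: str = "sim",
                      rng: np.random.Generator | None = None
                      ) -> HaplotypeFrequencyTable:
    """Synthetic per-window founder-haplotype frequencies with injected
    sweeps against an autocorrelated drift-like background."""
    rng = rng if rng is not None else spec.rng()
    # pre-smoothing concentration such that blending `span` windows gives
    # the requested effective marginal concentration (averaging k Dirichlet
    # draws divides the variance around 1/19 by ~k)
    raw_conc = max((spec.concentration + 1.0) / spec.smoothing_span - 1.0, 0.05)
    alpha = np.full(N_FOUNDERS, raw_conc / N_FOUNDERS)

    grid = spec.layout.windows(spec.window_size, spec.window_step)
    blocks = []
    for chrom, g in grid.groupby("chrom", sort=False):
        n_w = len(g)
        freqs = rng.dirichlet(alpha, size=n_w)
        if spec.smoothing_span > 1:
            freqs = uniform_filter1d(freqs, size=spec.smoothing_span,
                                     axis=0, mode="reflect")
            freqs /= freqs.sum(axis=1, keepdims=True)
        blocks.append((chrom, freqs))

    freq_by_chrom = dict(blocks)
    for sw in spec.sweeps:
        if sw.chrom not in freq_by_chrom:
            raise ValidationError(f"unknown chromosome {sw.chrom}")
        freqs = freq_by_chrom[sw.chrom]
        stop = sw.first_window + sw.n_windows
        if stop > len(freqs):
            raise ValidationError("sweep window range outside chromosome")
        cols = [FOUNDERS.index(f) for f in sw.founders]
        others = [i for i in range(N_FOUNDERS) if i not in cols]
        seg = freqs[sw.first_window:stop]
        rest_mass = seg[:, others].sum(axis=1)
        seg[:, cols] = sw.target_frequency / len(cols)
        seg[:, others] *= ((1.0 - sw.target_frequency) / rest_mass)[:, None]

    data = grid.copy()
    mat = np.vstack([freq_by_chrom[c] for c, _ in spec.layout.chromosomes
                     if c in set(grid["chrom"])])
    for j, f in enumerate(FOUNDERS):
        data[f] = mat[:, j]
    return HaplotypeFrequencyTable.from_dataframe(population_id, data)


# ---------------------------------------------------------------------------
# Phenotype fixtures
# ---------------------------------------------------------------------------

def _breed_breeding_values(bv_sire: np.ndarray, bv_dam: np.ndarray,
                           Va: float, rng: np.random.Generator) -> np.ndarray:
    """Mid-parent value plus Mendelian segregation noise.

    The segregation variance is sized to restore the additive variance to
    its base value Va each generation (floored at the classical Va/2), so
    the fixture's declared heritability stays the truth throughout the
    experiment instead of eroding as selection depletes the between-family
    variance.
    """
    mid = 0.5 * (bv_sire + bv_dam)
    if Va <= 0:
        return mid
    seg_var = max(Va - float(np.var(mid)), Va / 2.0)
    return mid + rng.normal(0.0, np.sqrt(seg_var), size=mid.shape)


def make_phenotype_fixture(spec: FixtureSpec, replicate: str = "A",
                           rng: np.random.Generator | None = None
                           ) -> PhenotypeTable:
    """Selection experiment with a known true narrow-sense heritability.

    Produces a directionally selected population and its paired random
    control sharing per-generation seasonal shifts, with `selected` flags
    marking the chosen parents each generation.
    """
    rng = rng if rng is not None else spec.rng()
    n, n_sel, k = spec.n_individuals, spec.n_selected, spec.progeny_per_cross
    n_crosses = n_sel // 2
    Vp = spec.phenotypic_sd ** 2
    Va = spec.true_h2 * Vp
    Ve = (1.0 - spec.true_h2) * Vp

    records = []
    bv = {"sel": rng.normal(0, np.sqrt(Va), n) if Va > 0 else np.zeros(n),
          "ctrl": rng.normal(0, np.sqrt(Va), n) if Va > 0 else np.zeros(n)}
    fam = {"sel": np.array(["founder"] * n), "ctrl": np.array(["founder"] * n)}

    for gen in range(spec.n_generations + 1):
        season = rng.normal(0.0, spec.seasonal_sd)
        next_bv, next_fam = {}, {}
        for pop in ("sel", "ctrl"):
            batch = rng.normal(0.0, spec.batch_sd)
            latent = (spec.baseline_branches + bv[pop] + season + batch
                      + rng.normal(0, np.sqrt(Ve), n))
            branches = np.maximum(np.rint(latent), 0).astype(int)
            if pop == "sel":
                order = np.lexsort((rng.random(n), -branches))
                chosen = order[:n_sel]
            else:
                chosen = rng.choice(n, n_sel, replace=False)
            selected = np.zeros(n, dtype=bool)
            if gen < spec.n_generations:
                selected[chosen] = True
            flowering = rng.normal(40.0, 5.0, n).clip(min=1.0)
            flowering[rng.random(n) < 0.05] = np.nan
            records.append(pd.DataFrame({
                "individual_id": [f"{pop}{replicate}_G{gen:02d}_I{i:03d}"
                                  for i in range(n)],
                "population_id": f"{pop}-{replicate}",
                "replicate": replicate,
                "generation": gen,
                "family_id": fam[pop],
                "branches": branches,
                "flowering_days": flowering,
                "treatment": "LN",
                "selected": selected,
            }))
            if gen < spec.n_generations:
                pairs = rng.permutation(chosen).reshape(n_crosses, 2)
                sires = np.repeat(pairs[:, 0], k)
                dams = np.repeat(pairs[:, 1], k)
                next_bv[pop] = _breed_breeding_values(
                    bv[pop][sires], bv[pop][dams], Va, rng)
                next_fam[pop] = np.repeat(
                    [f"{pop}{replicate}_G{gen + 1:02d}_F{j:02d}"
                     for j in range(n_crosses)], k)
        bv, fam = next_bv, next_fam
    return PhenotypeTable.from_dataframe(pd.concat(records, ignore_index=True))


def make_plasticity_fixture(spec: FixtureSpec, replicate: str = "A",
                            rng: np.random.Generator | None = None
                            ) -> PhenotypeTable:
    """Final-generation families split across HN/LN with a known mean
    plasticity shift (``spec.plasticity_shift`` branches, HN minus LN)."""
    rng = rng if rng is not None else spec.rng()
    n_fam = spec.n_selected // 2
    half = spec.progeny_per_cross // 2
    records = []
    for j in range(n_fam):
        ln_mean = spec.baseline_branches + rng.normal(0, 1)
        delta = rng.normal(spec.plasticity_shift, 1.0)
        for t, mean in (("LN", ln_mean), ("HN", ln_mean + delta)):
            vals = np.maximum(np.rint(rng.normal(mean, 1.0, half)), 0).astype(int)
            records.append(pd.DataFrame({
                "individual_id": [f"plas{replicate}_F{j:02d}_{t}_{i}"
                                  for i in range(half)],
                "population_id": f"plas-{replicate}",
                "replicate": replicate,
                "generation": spec.n_generations,
                "family_id": f"F{j:02d}",
                "branches": vals,
                "flowering_days": np.nan,
                "treatment": t,
                "selected": False,
            }))
    return PhenotypeTable.from_dataframe(pd.concat(records, ignore_index=True))


# ---------------------------------------------------------------------------
# Pedigree fixtures
# ---------------------------------------------------------------------------

def make_pedigree_fixture(spec: FixtureSpec,
                          rng: np.random.Generator | None = None
                          ) -> PedigreeTable:
    """Experiment-shaped pedigree: per generation, 40 parents paired into
    20 disjoint crosses of 10 progeny each (census 200).

    ``sibling_enrichment`` > 0 biases parent sampling towards families
    with a high random family value (a stand-in for a heritable selected
    trait), concentrating ancestry and raising inbreeding; at 0 the
    parents are a uniform draw.
    """
    rng = rng if rng is not None else spec.rng()
    n, n_sel, k = spec.n_individuals, spec.n_selected, spec.progeny_per_cross
    n_crosses = n_sel // 2
    rows = [pd.DataFrame({
        "individual_id": [f"P_G00_I{i:03d}" for i in range(n)],
        "sire_id": pd.Series([None] * n, dtype=object),
        "dam_id": pd.Series([None] * n, dtype=object),
        "generation": 0})]
    ids = rows[0]["individual_id"].to_numpy()
    families = np.arange(n) // k  # founders: arbitrary grouping, unused at e=0

    for gen in range(1, spec.n_generations + 1):
        if spec.sibling_enrichment > 0:
            fam_value = rng.standard_normal(families.max() + 1)
            w = np.exp(spec.sibling_enrichment * fam_value[families])
            p = w / w.sum()
        else:
            p = None
        chosen = rng.choice(n, n_sel, replace=False, p=p)
        pairs = rng.permutation(chosen).reshape(n_crosses, 2)
        sires = np.repeat(pairs[:, 0], k)
        dams = np.repeat(pairs[:, 1], k)
        new_ids = np.array([f"P_G{gen:02d}_I{i:03d}" for i in range(n)])
        rows.append(pd.DataFrame({
            "individual_id": new_ids,
            "sire_id": ids[sires],
            "dam_id": ids[dams],
            "generation": gen}))
        ids = new_ids
        families = np.arange(n) // k
    return PedigreeTable.from_dataframe(pd.concat(rows, ignore_index=True))


def make_wright_fisher_pedigree(n_parents: int = 40, n_offspring: int = 200,
                                n_generations: int = 10,
                                rng: np.random.Generator | None = None
                                ) -> PedigreeTable:
    """Idealised random-mating pedigree: each offspring draws two distinct
    parents uniformly (with replacement across offspring) from a random
    subset of ``n_parents`` individuals, giving the textbook heterozygosity
    decay rate 1/(2 n_parents) per generation."""
    rng = rng if rng is not None else np.random.default_rng()
    rows = [pd.DataFrame({
        "individual_id": [f"W_G00_I{i:03d}" for i in range(n_offspring)],
        "sire_id": pd.Series([None] * n_offspring, dtype=object),
        "dam_id": pd.Series([None] * n_offspring, dtype=object),
        "generation": 0})]
    ids = rows[0]["individual_id"].to_numpy()
    for gen in range(1, n_generations + 1):
        parents = rng.choice(len(ids), n_parents, replace=False)
        # draw two distinct parents per offspring
        sire_pos = rng.integers(0, n_parents, n_offspring)
        dam_pos = rng.integers(0, n_parents - 1, n_offspring)
        dam_pos[dam_pos >= sire_pos] += 1
        sires = parents[sire_pos]
        dams = parents[dam_pos]
        new_ids = np.array([f"W_G{gen:02d}_I{i:03d}" for i in range(n_offspring)])
        rows.append(pd.DataFrame({
            "individual_id": new_ids,
            "sire_id": ids[sires],
            "dam_id": ids[dams],
            "generation": gen}))
        ids = new_ids
    return PedigreeTable.from_dataframe(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# SNP fixtures
# ---------------------------------------------------------------------------

def make_snp_fixture(spec: FixtureSpec, hap_table: HaplotypeFrequencyTable,
                     rng: np.random.Generator | None = None) -> SnpTable:
    """SNPs whose pooled generation-10 frequencies follow the supplied
    haplotype-frequency table (sum of the carrier founders' window
    frequencies plus small noise); ~50% of SNPs are private to one founder."""
    rng = rng if rng is not None else spec.rng()
    layout = spec.layout
    lengths = np.array([l for _, l in layout.chromosomes], dtype=float)
    per_chrom = np.maximum(
        np.rint(spec.n_snps * lengths / lengths.sum()).astype(int), 1)

    hap = hap_table.data
    freq_mat = hap_table.frequencies
    records = []
    for (chrom, length), m in zip(layout.chromosomes, per_chrom):
        sub = hap[hap["chrom"] == chrom]
        if sub.empty:
            raise ValidationError(f"haplotype table lacks chromosome {chrom}")
        pos = np.sort(rng.integers(0, length, size=m))
        starts = sub["start"].to_numpy()
        win = np.clip(np.searchsorted(starts, pos, side="right") - 1,
                      0, len(sub) - 1)
        win_freqs = freq_mat[sub.index.to_numpy()[win]]
        for p, wf in zip(pos, win_freqs):
            if rng.random() < 0.5:
                carriers = frozenset({FOUNDERS[rng.integers(0, N_FOUNDERS)]})
            else:
                size = int(rng.integers(2, 10))
                carriers = frozenset(
                    rng.choice(FOUNDERS, size=size, replace=False))
            f = sum(wf[FOUNDERS.index(c)] for c in carriers)
            f = float(np.clip(f + rng.normal(0, 0.01), 0.0, 1.0))
            records.append((chrom, int(p), carriers, f))
    df = pd.DataFrame(records, columns=["chrom", "pos", "carriers", "freq"])
    return SnpTable.from_dataframe(df)
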