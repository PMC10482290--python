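"""Pedigree-based inbreeding and gene-drop null distributions.

Inbreeding coefficients come from the recursive additive-relationship
construction on a generation-ordered pedigree: founders are unrelated and
non-inbred, kinship(a, a) = (1 + F_a)/2, and an individual's kinship with
anyone born earlier is the average of its parents' kinships with that
individual.  F(x) is the kinship of x's parents.  An individual with one
known and one missing parent is treated as having an unrelated, non-inbred
phantom parent.

Gene dropping assigns every founder two alleles drawn i.i.d. uniform over
the 19 founder states ("equal starting frequency" read as equal expected
frequency) and transmits them through the pedigree by fair Mendelian
sampling, independently for each simulated locus.  The expected
heterozygosity of the final generation's pooled allele frequencies (2N
genes) gives the population-specific neutral null distribution used to
z-scale observed genome scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import N_FOUNDERS, PedigreeTable, ValidationError

logger = logging.getLogger("magicsweep")


@dataclass
class InbreedingReport:
    per_individual: pd.DataFrame  # individual_id, generation, F
    per_generation: pd.DataFrame  # generation, mean_F, se_F


@dataclass
class NullDistribution:
    """Neutral final-generation He values from gene dropping."""

    population_id: str
    values: np.ndarray
    mean: float
    sd: float


def _ordered_parent_indices(ped: PedigreeTable) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Pedigree sorted by generation plus integer parent indices (-1 missing)."""
    df = ped.data.sort_values("generation", kind="stable").reset_index(drop=True)
    pos = {iid: i for i, iid in enumerate(df["individual_id"])}
    sire = np.array([pos.get(p, -1) if pd.notna(p) else -1 for p in df["sire_id"]])
    dam = np.array([pos.get(p, -1) if pd.notna(p) else -1 for p in df["dam_id"]])
    return df, sire, dam


def inbreeding_coefficients(ped: PedigreeTable) -> InbreedingReport:
    """Per-individual inbreeding coefficients F and per-generation summary."""
    df, sire, dam = _ordered_parent_indices(ped)
    n = len(df)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            row = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            row = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            row = np.zeros(i)
            A[i, i] = 1.0
        A[i, :i] = row
        A[:i, i] = row
    F = np.diag(A) - 1.0
    per_ind = pd.DataFrame({
        "individual_id": df["individual_id"],
        "generation": df["generation"],
        "F": F})
    per_gen = (per_ind.groupby("generation")["F"]
               .agg(mean_F="mean",
                    se_F=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
               .reset_index())
    return InbreedingReport(per_ind, per_gen)


def gene_drop(ped: PedigreeTable, n_loci: int, rng: np.random.Generator,
              *, unique_founder_alleles: bool = False) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop alleles through the pedigree at ``n_loci`` independent loci.

    Returns the generation-ordered pedigree frame and an
    ``(n_individuals, 2, n_loci)`` allele array.  With
    ``unique_founder_alleles`` every founder gene gets a globally unique
    label (for identity-by-descent bookkeeping); otherwise founder alleles
    are i.i.d. uniform over the 19 states.  A missing parent acts as an
    unrelated phantom: its gamete is drawn like a fresh founder gamete.
    """
    if n_loci < 1:
        raise ValidationError("n_loci must be >= 1")
    df, sire, dam = _ordered_parent_indices(ped)
    n = len(df)
    dtype = np.int32 if unique_founder_alleles else np.int16
    alleles = np.empty((n, 2, n_loci), dtype=dtype)
    next_unique = 0

    def founder_gamete(i: int, slot: int) -> None:
        nonlocal next_unique
        if unique_founder_alleles:
            alleles[i, slot, :] = next_unique
            next_unique += 1
        else:
            alleles[i, slot, :] = rng.integers(0, N_FOUNDERS, size=n_loci)

    for i in range(n):
        for slot, p in enumerate((sire[i], dam[i])):
            if p < 0:
                founder_gamete(i, slot)
            else:
                pick = rng.integers(0, 2, size=n_loci)
                alleles[i, slot, :] = alleles[p, pick, np.arange(n_loci)]
    return df, alleles


def gene_drop_null(ped: PedigreeTable, n_null_loci: int,
                   rng: np.random.Generator,
                   population_id: str = "") -> NullDistribution:
    """Neutral He distribution at the final pedigree generation.

    For each locus, founder alleles are dropped through the pedigree and
    He = 1 - sum p_i^2 computed from the final generation's pooled allele
    frequencies (both alleles of every individual).
    """
    df, alleles = gene_drop(ped, n_null_loci, rng)
    last = df["generation"].max()
    final = alleles[(df["generation"] == last).to_numpy()]
    if final.size == 0:
        raise ValidationError("empty final generation")
    two_n = final.shape[0] * 2
    genes = final.reshape(-1, n_null_loci)
    he = np.empty(n_null_loci)
    offset = genes.astype(np.int64) + N_FOUNDERS * np.arange(n_null_loci)[None, :]
    counts = np.bincount(offset.ravel(), minlength=N_FOUNDERS * n_null_loci)
    p = counts.reshape(n_null_loci, N_FOUNDERS) / two_n
    he = 1.0 - (p ** 2).sum(axis=1)
    return NullDistribution(population_id=population_id, values=he,
                            mean=float(he.mean()), sd=float(he.std(ddof=1)))


def expected_heterozygosity_decay(H0: float, N: float, t: float) -> float:
    """Neutral drift expectation H_t = H_0 (1 - 1/(2N))^t."""
    if not 0 <= H0 <= 1:
        raise ValueError("H0 must lie in [0, 1]")
    if N < 1 or t < 0:
        raise ValueError("require N >= 1 and t >= 0")
    return H0 * (1.0 - 1.0 / (2.0 * N)) ** t


def null_summary(null: NullDistribution) -> tuple[float, float]:
    """Sample mean and SD of the null He values, for z-scaling scans.

    A degenerate (zero-SD) distribution is flagged with a warning: z-scores
    against it are undefined.
    """
    if null.values.size < 2:
        raise ValueError("need at least 2 null loci")
    mean = float(null.values.mean())
    sd = float(null.values.std(ddof=1))
    if sd == 0:
        logger.warning("degenerate null distribution (SD = 0) for %s",
                       null.population_id or "<unnamed>")
    return mean, sd
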