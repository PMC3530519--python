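"""Three classical microsatellite bottleneck detectors.

1. *Heterozygosity excess*: after a decline, rare alleles are lost
   faster than gene diversity, so observed He exceeds the equilibrium
   expectation conditional on the observed allele count.  The
   equilibrium reference distribution is simulated by coalescent
   replicates conditioned on k, and loci are combined with a one-tailed
   Wilcoxon signed-rank test.
2. *Mode shift*: at mutation-drift equilibrium the pooled
   allele-frequency spectrum is L-shaped (the rarest class is the
   modal class); a recent bottleneck empties the rare class.
3. *M-ratio*: M = k / (range in allelic states); allele loss shrinks k
   faster than the range, so low M flags a decline.  Significance comes
   from the 5% quantile of equilibrium multi-locus mean M (M-critical),
   simulated at a grid of theta values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._kernels import he_conditional_on_k, m_critical_null
from .dataset import GenotypeDataset
from .io import allele_counts
from .mutation import MutationModel
from .stats import unbiased_he

logger = logging.getLogger(__name__)

#: default TPM for heterozygosity-excess testing (variance convention)
TPM_DEFAULT = MutationModel.tpm_variance(p_single=0.95, variance=12.0)
#: default TPM for M-ratio critical values (mean convention)
TPM_MRATIO = MutationModel.tpm_mean(p_single=0.90, mean=3.5, mu=5e-4)


# ----------------------------------------------------------------------
# heterozygosity excess


@dataclass
class HetExcessResult:
    """Per-locus equilibrium comparison plus the overall Wilcoxon p."""

    locus_names: list[str]
    he_obs: np.ndarray
    heq_mean: np.ndarray
    heq_sd: np.ndarray
    std_diff: np.ndarray
    n_excess: int
    p_value: float
    excluded_loci: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.locus_names,
                "He_obs": self.he_obs,
                "Heq_mean": self.heq_mean,
                "Heq_sd": self.heq_sd,
                "std_diff": self.std_diff,
            }
        ).set_index("locus")


def het_excess_test(
    group: GenotypeDataset,
    model: MutationModel = TPM_DEFAULT,
    reps: int = 5000,
    seed: int = 0,
) -> HetExcessResult:
    """Wilcoxon one-tailed test for heterozygosity excess.

    For each polymorphic locus the equilibrium He distribution is
    simulated conditional on the observed allele count and sample size;
    the signed differences He_obs - mean(Heq) feed a one-tailed
    Wilcoxon signed-rank test (exact for <= 25 informative loci).
    """
    counts = allele_counts(group)
    names, he_obs, heq_mean, heq_sd, excluded = [], [], [], [], []
    rng = np.random.default_rng(seed)
    theta0 = model.theta if model.theta else 2.0
    for locus, c in zip(group.loci, counts):
        n_genes = sum(c.values())
        k = len(c)
        if k < 2 or n_genes < 4:
            excluded.append(locus.name)
            logger.info("het_excess_test: excluding monomorphic locus %s", locus.name)
            continue
        he, attempts = he_conditional_on_k(
            n_genes,
            k,
            theta0,
            model.p_single,
            model.p_geom,
            model.multistep_shift,
            reps,
            int(rng.integers(2**31)),
        )
        if he.size < max(100, reps // 10):
            excluded.append(locus.name)
            logger.warning(
                "het_excess_test: locus %s rejected-sampling starved "
                "(%d/%d in %d attempts)",
                locus.name,
                he.size,
                reps,
                attempts,
            )
            continue
        names.append(locus.name)
        he_obs.append(unbiased_he(c))
        heq_mean.append(float(he.mean()))
        heq_sd.append(float(he.std(ddof=1)))
    if not names:
        raise ValueError("no polymorphic loci: heterozygosity-excess test undefined")
    if len(names) < 4:
        logger.warning("het_excess_test: only %d informative loci", len(names))
    he_obs = np.array(he_obs)
    heq_mean = np.array(heq_mean)
    heq_sd = np.array(heq_sd)
    diffs = he_obs - heq_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        std_diff = np.where(heq_sd > 0, diffs / heq_sd, np.nan)
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        p = 1.0
    else:
        method = "exact" if nonzero.size <= 25 else "approx"
        p = float(
            sps.wilcoxon(nonzero, alternative="greater", method=method).pvalue
        )
    return HetExcessResult(
        locus_names=names,
        he_obs=he_obs,
        heq_mean=heq_mean,
        heq_sd=heq_sd,
        std_diff=std_diff,
        n_excess=int((diffs > 0).sum()),
        p_value=p,
        excluded_loci=excluded,
    )


# ----------------------------------------------------------------------
# mode shift


@dataclass
class ModeShiftResult:
    shifted: bool
    class_counts: np.ndarray  # ten frequency classes of width 0.1

    def to_frame(self) -> pd.DataFrame:
        edges = [f"[{i / 10:.1f},{(i + 1) / 10:.1f})" for i in range(10)]
        return pd.DataFrame({"class": edges, "alleles": self.class_counts}).set_index(
            "class"
        )


def mode_shift_test(group: GenotypeDataset, min_individuals: int = 30) -> ModeShiftResult:
    """Graphical mode-shift test on the pooled allele-frequency spectrum.

    Alleles from all loci are binned into ten frequency classes of
    width 0.1; the spectrum is "shifted" when the rare class [0, 0.1)
    holds strictly fewer alleles than some higher class.  Requires at
    least 30 typed individuals (high type-I error below that).
    """
    if group.n_individuals < min_individuals:
        raise ValueError(
            f"mode-shift test needs >= {min_individuals} individuals, "
            f"got {group.n_individuals}"
        )
    counts = allele_counts(group)
    bins = np.zeros(10, dtype=int)
    for c in counts:
        n_genes = sum(c.values())
        if n_genes == 0 or len(c) < 2:
            continue
        for cnt in c.values():
            freq = cnt / n_genes
            b = min(int(freq * 10), 9)
            bins[b] += 1
    shifted = bool((bins[1:] > bins[0]).any())
    return ModeShiftResult(shifted=shifted, class_counts=bins)


def mode_shift_from_frequencies(freqs_per_locus: Sequence[np.ndarray]) -> ModeShiftResult:
    """Mode-shift verdict straight from per-locus allele frequencies
    (used by power simulations that bypass the dataset container)."""
    bins = np.zeros(10, dtype=int)
    for freqs in freqs_per_locus:
        freqs = np.asarray(freqs, dtype=float)
        freqs = freqs[freqs > 0]
        if freqs.size < 2:
            continue
        for f in freqs:
            bins[min(int(f * 10), 9)] += 1
    return ModeShiftResult(shifted=bool((bins[1:] > bins[0]).any()), class_counts=bins)


# ----------------------------------------------------------------------
# M-ratio


@dataclass
class MRatioResult:
    locus_names: list[str]
    m_per_locus: np.ndarray
    mean_m: float
    critical: dict[float, float] = field(default_factory=dict)  # theta -> cutoff

    def significant_at(self, theta: float) -> bool:
        return self.mean_m < self.critical[theta]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"locus": self.locus_names, "M": self.m_per_locus}
        ).set_index("locus")


def m_ratio(group: GenotypeDataset) -> MRatioResult:
    """Per-locus and mean M = k / s, s = (max - min) + 1 allelic states.

    The occupied-state denominator bounds M in (0, 1]; monomorphic loci
    are excluded from the multi-locus mean.
    """
    counts = allele_counts(group)
    names, ms = [], []
    for locus, c in zip(group.loci, counts):
        if len(c) < 2:
            continue
        sizes = np.array(sorted(c))
        s = sizes.max() - sizes.min() + 1
        names.append(locus.name)
        ms.append(len(c) / s)
    if not ms:
        raise ValueError("all loci monomorphic: M-ratio undefined")
    ms = np.array(ms)
    return MRatioResult(locus_names=names, m_per_locus=ms, mean_m=float(ms.mean()))


def m_critical(
    n_ind: int,
    n_loci: int,
    theta: float,
    model: MutationModel = TPM_MRATIO,
    reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Simulated significance cutoff for the mean M-ratio.

    The alpha-quantile of the equilibrium distribution of the
    multi-locus mean M for 2*n_ind gene copies at the given theta
    (theta = 4*Ne*mu); an observed mean M below the cutoff is a
    significant bottleneck signal.
    """
    if reps < 1000:
        logger.warning("m_critical: reps=%d gives an unstable quantile", reps)
    null = m_critical_null(
        2 * n_ind,
        n_loci,
        reps,
        theta,
        model.p_single,
        model.p_geom,
        model.multistep_shift,
        seed,
    )
    return float(np.quantile(null, alpha))


# ----------------------------------------------------------------------
# battery


@dataclass
class BottleneckReport:
    """Table-shaped report of all three tests for a set of groups."""

    rows: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", float_format="%.4g")


def bottleneck_battery(
    group: GenotypeDataset,
    deme_partition: bool = False,
    tpm_variants: Sequence[float] = (0.05, 0.20),
    theta_grid: Sequence[float] = (1.0, 2.0, 5.0, 10.0),
    het_reps: int = 5000,
    mc_reps: int = 10_000,
    seed: int = 0,
    label: Optional[str] = None,
    _mc_cache: Optional[dict] = None,
) -> BottleneckReport:
    """Run all three detectors on a group, optionally per deme.

    One row per analysis unit (pooled group first, then each deme when
    ``deme_partition``): heterozygosity-excess p at each TPM multistep
    proportion, the mode-shift verdict, mean M, and M-critical cutoffs
    over the theta grid.
    """
    units: list[tuple[str, GenotypeDataset]] = [
        (label or "/".join(group.populations()) or "all", group)
    ]
    if deme_partition:
        if group.deme is None:
            raise ValueError("deme_partition requested but dataset has no deme labels")
        for d in sorted({str(x) for x in group.deme}):
            units.append((f"{units[0][0]} - {d}", group.select(deme=d)))
    mc_cache = _mc_cache if _mc_cache is not None else {}
    rows = []
    rng = np.random.default_rng(seed)
    for name, sub in units:
        row: dict = {"group": name, "n": sub.n_individuals}
        for p_multi in tpm_variants:
            model = MutationModel.tpm_variance(1.0 - p_multi, 12.0)
            try:
                res = het_excess_test(
                    sub, model, reps=het_reps, seed=int(rng.integers(2**31))
                )
                row[f"he_excess_p_tpm{int(p_multi * 100)}"] = res.p_value
            except ValueError as e:
                row[f"he_excess_p_tpm{int(p_multi * 100)}"] = np.nan
                logger.warning("het excess failed for %s: %s", name, e)
        try:
            row["mode_shift"] = "Yes" if mode_shift_test(sub).shifted else "No"
        except ValueError:
            row["mode_shift"] = "-"  # sample too small, mirrored refusal
        try:
            mr = m_ratio(sub)
            row["M"] = mr.mean_m
            for th in theta_grid:
                key = (sub.n_individuals, sub.n_loci, th)
                if key not in mc_cache:
                    mc_cache[key] = m_critical(
                        sub.n_individuals,
                        sub.n_loci,
                        th,
                        reps=mc_reps,
                        seed=int(rng.integers(2**31)),
                    )
                row[f"M_crit_theta{th:g}"] = mc_cache[key]
            row["M_significant"] = (
                "Yes"
                if any(row["M"] < row[f"M_crit_theta{th:g}"] for th in theta_grid)
                else "No"
            )
        except ValueError as e:
            row["M"] = np.nan
            logger.warning("M-ratio failed for %s: %s", name, e)
        rows.append(row)
    return BottleneckReport(rows=pd.DataFrame(rows).set_index("group"))
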