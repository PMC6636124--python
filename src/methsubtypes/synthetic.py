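"""Synthetic 450K-style tumor cohorts with planted prognostic subtypes.

The generator emulates the statistical structure the downstream analysis
assumes: beta-distributed methylation values in [0, 1] with K latent
subtypes, each carrying planted hyper-/hypomethylated CpG sets; survival
times whose hazard depends on subtype; ordinal clinical covariates
(T/N/M, stage, grade) statistically tied to subtype while sex is
independent; completely-at-random missing entries; and manifest-flagged
bad probes (cross-reactive, sex-chromosome, SNP-overlap).

Randomness uses a single master seed with independent child streams per
concern (subtype labels, methylation, survival, clinical, missingness,
manifest), so toggling one feature does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CLINICAL_COLUMNS

_STREAMS = ("labels", "methylation", "survival", "clinical", "missing", "manifest")

# global ordinal distributions, loosely shaped on renal-cohort clinical tables
_GLOBAL_T = np.array([0.50, 0.12, 0.33, 0.05])
_GLOBAL_N = np.array([0.90, 0.10])
_GLOBAL_M = np.array([0.85, 0.15])
_GLOBAL_STAGE = np.array([0.48, 0.11, 0.22, 0.19])
_GLOBAL_GRADE = np.array([0.05, 0.42, 0.40, 0.13])

# strength of the subtype->clinical coupling at clinical_assoc_strength = 1:
# exponential tilt of the ordinal categoricals and the age mean offset
# (years) between the best- and worst-prognosis subtype.  The binary N/M
# attributes and the T category (whose mass sits mostly in T1/T3) get a
# stronger tilt than stage/grade: a rare or lumpy categorical needs a
# larger shift for the same detectable association.
_TILT_AMPLITUDE = 1.2
_T_TILT_AMPLITUDE = 1.9
_BINARY_TILT_AMPLITUDE = 1.8
_AGE_AMPLITUDE = 12.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated methylation cohort.

    Defaults mirror the design of the renal 450K study this pipeline
    targets: 307 tumors split roughly 50/50 into train/test, K = 7 latent
    prognostic subtypes, planted subtype-specific CpGs shifted by
    ``delta`` in mean beta value, and beta-value noise at precision 30
    (shape parameters mean*precision, (1-mean)*precision).
    """

    n_samples: int = 307
    n_cpgs: int = 2000
    n_subtypes: int = 7
    mixing_proportions: tuple[float, ...] | None = None
    n_specific_per_subtype: int = 100
    delta: float = 0.3
    direction_mix: float = 0.5
    beta_precision: float = 30.0
    baseline_mean_range: tuple[float, float] = (0.35, 0.65)
    hazard_rates: tuple[float, ...] | None = None
    censor_window_days: float = 5500.0
    min_followup_days: float = 30.0
    missing_frac: float = 0.02
    n_flagged_crossreactive: int = 20
    n_sexchrom: int = 20
    n_snp: int = 20
    clinical_assoc_strength: float = 0.45
    seed: int = 0

    def resolved_mixing(self) -> np.ndarray:
        if self.mixing_proportions is None:
            return np.full(self.n_subtypes, 1.0 / self.n_subtypes)
        return np.asarray(self.mixing_proportions, dtype=float)

    def resolved_hazards(self) -> np.ndarray:
        """Per-subtype exponential event rates (events/day).

        Default (K = 7): a two-tier prognostic profile — indolent
        subtypes 1, 2, 4, 6 (rates 1/7000..1/4800 per day) and
        aggressive subtypes 3, 5, 7 (1/650..1/350) — so subtypes 1 and 2
        carry the best prognosis and 3 and 7 the worst, and every
        subtype's hazard sits well away from the cohort average (its
        marker CpGs stay survival-associated even after clinical
        adjustment).  For other K: geometric spacing between 1/4000 and
        1/500.
        """
        if self.hazard_rates is None:
            if self.n_subtypes == 7:
                return np.array([1 / 7000, 1 / 6000, 1 / 550, 1 / 5200,
                                 1 / 650, 1 / 4800, 1 / 350])
            return np.geomspace(1 / 4000, 1 / 500, self.n_subtypes)
        return np.asarray(self.hazard_rates, dtype=float)

    def validate(self) -> None:
        if self.n_subtypes < 2:
            raise ValueError("need at least 2 subtypes")
        mix = self.resolved_mixing()
        if len(mix) != self.n_subtypes or abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("mixing_proportions must have length K and sum to 1")
        lo, hi = self.baseline_mean_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("baseline_mean_range must be inside (0, 1)")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1] (0 = no planted signal)")
        if self.delta > 0 and (lo - self.delta <= 0.0 or hi + self.delta >= 1.0):
            raise ValueError(
                "delta pushes shifted means outside (0, 1): narrow "
                "baseline_mean_range or shrink delta")
        if self.n_subtypes * self.n_specific_per_subtype > self.n_cpgs:
            raise ValueError("more planted specific CpGs than probes")
        n_flagged = self.n_flagged_crossreactive + self.n_sexchrom + self.n_snp
        n_specific = self.n_subtypes * self.n_specific_per_subtype
        if n_flagged + n_specific > self.n_cpgs:
            raise ValueError("flagged plus specific probes exceed n_cpgs")
        if not 0.0 <= self.missing_frac <= 1.0:
            raise ValueError("missing_frac must be in [0, 1]")
        hz = self.resolved_hazards()
        if len(hz) != self.n_subtypes or (hz <= 0).any():
            raise ValueError("hazard_rates must be K positive rates")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the planted ground truth."""

    methylation: pd.DataFrame      # probes x samples, NaN = missing
    clinical: pd.DataFrame         # indexed by sample ID
    manifest: pd.DataFrame         # indexed by probe ID
    true_labels: pd.Series         # subtype index (1..K) per sample
    true_specific: dict[int, list[tuple[str, str]]]  # cluster -> [(probe, direction)]
    spec: CohortSpec

    @property
    def true_specific_probes(self) -> set[str]:
        return {p for calls in self.true_specific.values() for p, _ in calls}


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    return {name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(_STREAMS, root.spawn(len(_STREAMS)))}


def _beta_sample(rng, mean, precision, size=None):
    a = np.asarray(mean) * precision
    b = (1.0 - np.asarray(mean)) * precision
    return rng.beta(a, b, size=size)


def _tilted_probs(base: np.ndarray, tilt: float) -> np.ndarray:
    """Shift categorical mass toward higher categories by exponential tilt."""
    w = base * np.exp(tilt * np.arange(len(base)))
    return w / w.sum()


def _draw_ordinal(rng, base: np.ndarray, tilts: np.ndarray,
                  labels0: np.ndarray, strength: float) -> np.ndarray:
    """Mixture draw: with prob `strength` from the subtype-tilted
    categorical, else from the global categorical."""
    n = len(labels0)
    out = np.empty(n, dtype=int)
    use_subtype = rng.random(n) < strength
    global_draw = rng.choice(len(base), size=n, p=base)
    for c in np.unique(labels0):
        mask = labels0 == c
        probs = _tilted_probs(base, tilts[c])
        sub_draw = rng.choice(len(base), size=mask.sum(), p=probs)
        out[mask] = np.where(use_subtype[mask], sub_draw, global_draw[mask])
    return out + 1  # 1-based ordinal codes (N/M corrected by caller)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort per the spec'd generative model.

    Probe g has baseline mean mu_g ~ Uniform(baseline_mean_range); a
    subtype-specific probe shifts the owning subtype's mean by +delta
    (hyper) or -delta (hypo), clipped into [0.01, 0.99].  Values are
    Beta(mean, precision) draws.  Survival = min(Exponential(rate of the
    sample's subtype), Uniform(0, censor_window)); clinical ordinals are
    subtype-tilted mixtures; age carries a small subtype offset; sex is
    independent of subtype.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rngs = _streams(spec.seed)
    K = spec.n_subtypes
    n, g = spec.n_samples, spec.n_cpgs

    sample_ids = [f"S{i:04d}" for i in range(n)]
    probe_ids = [f"cg{i:08d}" for i in range(g)]

    labels0 = rngs["labels"].choice(K, size=n, p=spec.resolved_mixing())

    # --- probe layout: flagged (null) probes first, then planted specific
    n_flagged = spec.n_flagged_crossreactive + spec.n_sexchrom + spec.n_snp
    specific_idx = np.arange(n_flagged, n_flagged + K * spec.n_specific_per_subtype)
    owner = np.full(g, -1)
    direction = np.full(g, "", dtype=object)
    rng_m = rngs["methylation"]
    for c in range(K):
        block = specific_idx[c * spec.n_specific_per_subtype:
                             (c + 1) * spec.n_specific_per_subtype]
        owner[block] = c
        hyper = rng_m.random(len(block)) < spec.direction_mix
        direction[block] = np.where(hyper, "hyper", "hypo")

    lo, hi = spec.baseline_mean_range
    mu = rng_m.uniform(lo, hi, size=g)
    means = np.tile(mu[:, None], (1, K))
    shift = np.where(direction == "hyper", spec.delta,
                     np.where(direction == "hypo", -spec.delta, 0.0))
    for c in range(K):
        means[owner == c, c] = mu[owner == c] + shift[owner == c]
    means = np.clip(means, 0.01, 0.99)

    values = _beta_sample(rng_m, means[:, labels0], spec.beta_precision,
                          size=(g, n))

    # --- survival
    rates = spec.resolved_hazards()
    rng_s = rngs["survival"]
    event_t = rng_s.exponential(1.0 / rates[labels0])
    censor_t = rng_s.uniform(0.0, spec.censor_window_days, size=n)
    followup = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)

    # --- clinical covariates (aggressiveness tracks hazard rank)
    rng_c = rngs["clinical"]
    hazard_rank = np.argsort(np.argsort(rates))           # 0 = best prognosis
    rank_scale = (hazard_rank - (K - 1) / 2) / max(K - 1, 1) * 2
    tilts = _TILT_AMPLITUDE * rank_scale
    binary_tilts = _BINARY_TILT_AMPLITUDE * rank_scale
    s = spec.clinical_assoc_strength
    T = _draw_ordinal(rng_c, _GLOBAL_T, _T_TILT_AMPLITUDE * rank_scale,
                      labels0, s)
    N = _draw_ordinal(rng_c, _GLOBAL_N, binary_tilts, labels0, s) - 1
    M = _draw_ordinal(rng_c, _GLOBAL_M, binary_tilts, labels0, s) - 1
    stage = _draw_ordinal(rng_c, _GLOBAL_STAGE, tilts, labels0, s)
    grade = _draw_ordinal(rng_c, _GLOBAL_GRADE, tilts, labels0, s)
    age_offset = _AGE_AMPLITUDE * (hazard_rank - (K - 1) / 2) / max(K - 1, 1) * 2
    age = rng_c.normal(60.0 + s * age_offset[labels0], 12.0)
    age = np.clip(age, 20.0, 95.0)
    sex = np.where(rng_c.random(n) < 0.5, "male", "female")

    clinical = pd.DataFrame(
        {
            "followup_days": followup,
            "event": event,
            "T": T,
            "N": N,
            "M": M,
            "stage": stage,
            "grade": grade,
            "age_years": age,
            "sex": sex,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )[CLINICAL_COLUMNS]

    # --- missingness, completely at random
    if spec.missing_frac > 0:
        mask = rngs["missing"].random((g, n)) < spec.missing_frac
        values = np.where(mask, np.nan, values)

    methylation = pd.DataFrame(values,
                               index=pd.Index(probe_ids, name="probe"),
                               columns=sample_ids)

    manifest = _make_manifest(spec, probe_ids, rngs["manifest"])

    true_specific = {
        c + 1: [(probe_ids[i], str(direction[i]))
                for i in specific_idx if owner[i] == c]
        for c in range(K)
    }
    true_labels = pd.Series(labels0 + 1, index=methylation.columns,
                            name="true_subtype")
    return SyntheticCohort(methylation, clinical, manifest, true_labels,
                           true_specific, spec)


def _make_manifest(spec: CohortSpec, probe_ids: Sequence[str],
                   rng: np.random.Generator) -> pd.DataFrame:
    g = len(probe_ids)
    n_cr, n_xy, n_snp = (spec.n_flagged_crossreactive, spec.n_sexchrom,
                         spec.n_snp)
    chromosome = rng.choice([str(i) for i in range(1, 23)], size=g)
    chromosome[n_cr:n_cr + n_xy] = rng.choice(["X", "Y"], size=n_xy)
    position = rng.integers(1, 250_000_000, size=g)
    features = rng.choice(
        ["TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "intergenic"],
        size=g, p=[0.13, 0.12, 0.10, 0.08, 0.35, 0.07, 0.15])
    n_genes = rng.choice([0, 1, 2], size=g, p=[0.15, 0.70, 0.15])
    gene_pool = [f"GENE{i:04d}" for i in range(max(g // 2, 10))]
    genes = [";".join(rng.choice(gene_pool, size=k, replace=False))
             for k in n_genes]
    cross_reactive = np.zeros(g, dtype=bool)
    cross_reactive[:n_cr] = True
    snp_overlap = np.zeros(g, dtype=bool)
    snp_overlap[n_cr + n_xy:n_cr + n_xy + n_snp] = True
    return pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": position,
            "genes": genes,
            "feature": features,
            "cross_reactive": cross_reactive,
            "snp_overlap": snp_overlap,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def null_pvalue_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Like :func:`generate_cohort` but survival is independent of subtype
    and of every probe (single hazard rate = geometric mean of the
    per-subtype rates): a type-I-error harness for the screening stage.
    """
    spec.validate()
    rate = float(np.exp(np.mean(np.log(spec.resolved_hazards()))))
    cohort = generate_cohort(spec)
    # redraw survival from an independent stream at the common rate
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(spec.seed, spawn_key=(1001,))))
    n = spec.n_samples
    event_t = rng.exponential(1.0 / rate, size=n)
    censor_t = rng.uniform(0.0, spec.censor_window_days, size=n)
    cohort.clinical["followup_days"] = np.minimum(event_t, censor_t)
    cohort.clinical["event"] = (event_t <= censor_t).astype(int)
    return cohort


# ---------------------------------------------------------------------------
# Cox-screen benchmark harnesses

def planted_effect_cohort(n_samples: int = 150, n_probes: int = 10,
                          beta: float = 1.0, baseline_rate: float = 1 / 1500,
                          censor_window_days: float = 3650.0,
                          seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """A cohort where probe 0 drives the hazard with log-hazard slope `beta`.

    The planted probe is a low-precision beta draw (Beta(0.25, 0.25), the
    bimodal shape typical of variable 450K CpGs), i.e. a maximally
    variable CpG, so the stated effect size is identifiable at modest n;
    remaining probes are prognostically inert.  Clinical covariates are
    drawn independently of survival.  Returns
    (methylation, clinical, planted_probe_id).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2001,)))
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    values = _beta_sample(rng, 0.5, 30.0, size=(n_probes, n_samples))
    x = rng.beta(0.25, 0.25, size=n_samples)  # bimodal, sd ~ 0.41
    values[0] = x
    event_t = rng.exponential(1.0 / (baseline_rate * np.exp(beta * x)))
    censor_t = rng.uniform(0.0, censor_window_days, size=n_samples)
    clinical = _independent_clinical(rng, sample_ids, event_t, censor_t)
    methylation = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe"),
                               columns=sample_ids)
    return methylation, clinical, probe_ids[0]


def confounded_probe_cohort(n_samples: int = 150, n_probes: int = 10,
                            stage_loghr: float = 0.7,
                            baseline_rate: float = 1 / 2500,
                            censor_window_days: float = 3650.0,
                            seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """A cohort where survival depends on clinical stage and probe 0 is a
    near-deterministic function of stage (tight beta noise around a
    stage-determined mean): the probe carries no prognostic information
    beyond stage, so a covariate-adjusted screen should reject it.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2002,)))
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    stage = rng.choice([1, 2, 3, 4], size=n_samples, p=_GLOBAL_STAGE)
    values = _beta_sample(rng, 0.5, 30.0, size=(n_probes, n_samples))
    stage_mean = 0.2 + 0.2 * (stage - 1)          # 0.2 .. 0.8
    values[0] = _beta_sample(rng, stage_mean, 400.0)
    event_t = rng.exponential(
        1.0 / (baseline_rate * np.exp(stage_loghr * (stage - 1))))
    censor_t = rng.uniform(0.0, censor_window_days, size=n_samples)
    clinical = _independent_clinical(rng, sample_ids, event_t, censor_t)
    clinical["stage"] = stage
    methylation = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe"),
                               columns=sample_ids)
    return methylation, clinical, probe_ids[0]


def _independent_clinical(rng, sample_ids, event_t, censor_t) -> pd.DataFrame:
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "followup_days": np.minimum(event_t, censor_t),
            "event": (event_t <= censor_t).astype(int),
            "T": rng.choice([1, 2, 3, 4], size=n, p=_GLOBAL_T),
            "N": rng.choice([0, 1], size=n, p=_GLOBAL_N),
            "M": rng.choice([0, 1], size=n, p=_GLOBAL_M),
            "stage": rng.choice([1, 2, 3, 4], size=n, p=_GLOBAL_STAGE),
            "grade": rng.choice([1, 2, 3, 4], size=n, p=_GLOBAL_GRADE),
            "age_years": np.clip(rng.normal(60.0, 12.0, size=n), 20.0, 95.0),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )[CLINICAL_COLUMNS]


def small_benchmark_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The planted-K recovery benchmark: K = 7 subtypes, 150 samples,
    700 probes all subtype-specific (100 per subtype) at delta = 0.3."""
    base = dict(n_samples=150, n_cpgs=700, n_subtypes=7,
                n_specific_per_subtype=100, delta=0.3,
                n_flagged_crossreactive=0, n_sexchrom=0, n_snp=0,
                missing_frac=0.0, seed=seed)
    base.update(overrides)
    return CohortSpec(**base)
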