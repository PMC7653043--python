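"""Synthetic FH-registry cohorts with the structure the analysis assumes.

No patient-level registry data are distributable, so this module generates
cohorts that emulate the published structure: PV-group mix (~64% PV-negative,
12% LDLR-null, 20% LDLR-defective, 4% APOB/PCSK9), group-specific baseline
LDL-C medians (log-normal around 206/256/248/205 mg/dL), the observed
maximal-regimen frequency mix with an escalation-policy bias toward
higher-intensity regimens in PV-positive patients, independent binomial SNP
dosages, and a multiplicative response model

    P_i = 100*f_g - 100*c*(S_i - E[S]) + eps_i,     eps ~ N(0, sd_P)
    delta%_i = min(100, P_i * E_i / 100)
    post_i = pre_i * (1 - delta%_i / 100)

where f_g is the group-level achieved fraction of the expected reduction,
S_i the weighted SNP score and c its per-unit effect.  Centring the score
term on its expectation keeps f_g interpretable as the group's typical
achieved fraction regardless of c.  The default noise and score-effect
magnitudes are calibrated to the registry-scale dispersion and the weak
score-response correlation; see docs/methods.md.

Randomness uses a single seed fanned out into named substreams (group,
baseline, regimen, agent, genotype, response, variant, follow-up), so
adding a downstream draw never perturbs upstream ones and a fixed seed
reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigValidationError
from .regimen import ExpectedReductionTable, Regimen, StatinDose
from .snpscore import DEFAULT_RSIDS, SNPWeight, placeholder_weights
from .variants import PVGroup, VariantClass, VariantRecord, Zygosity

_STREAMS = ("group", "baseline", "regimen", "agent", "genotype", "response", "variant", "followup")

#: Maximal statin-based regimens and their observed cohort frequencies,
#: ordered by intensity (expected reduction 40..70%).
REGIMEN_FREQUENCIES: tuple[tuple[float, bool, int], ...] = (
    # (atorvastatin-equivalent dose, ezetimibe, count of 83)
    (10.0, False, 6),
    (20.0, False, 22),
    (40.0, False, 7),
    (80.0, False, 5),
    (20.0, True, 10),
    (40.0, True, 21),
    (80.0, True, 12),
)

DEFAULT_GROUP_PROPORTIONS: dict[str, float] = {
    PVGroup.PV_NEGATIVE.value: 53 / 83,
    PVGroup.LDLR_NULL.value: 10 / 83,
    PVGroup.LDLR_DEFECTIVE.value: 17 / 83,
    PVGroup.APOB_PCSK9.value: 3 / 83,
}

DEFAULT_BASELINE_MEDIAN: dict[str, float] = {
    PVGroup.PV_NEGATIVE.value: 206.0,
    PVGroup.LDLR_NULL.value: 256.0,
    PVGroup.LDLR_DEFECTIVE.value: 248.0,
    PVGroup.APOB_PCSK9.value: 205.0,
    PVGroup.COMPOUND_OR_HOMOZYGOUS.value: 320.0,
}

DEFAULT_RESPONSE_FACTOR: dict[str, float] = {
    PVGroup.PV_NEGATIVE.value: 0.953,
    PVGroup.LDLR_NULL.value: 0.769,
    PVGroup.LDLR_DEFECTIVE.value: 0.886,
    PVGroup.APOB_PCSK9.value: 0.895,
    PVGroup.COMPOUND_OR_HOMOZYGOUS.value: 0.70,
}

#: Placeholder effect-allele frequencies (real East-Asian frequencies are
#: config inputs, not claims).
DEFAULT_ALLELE_FREQS: dict[str, float] = {
    "rs651007": 0.35,
    "rs599839": 0.25,
    "rs12654264": 0.45,
    "rs2738446": 0.30,
}

# Variant pools drawn from for PV-positive patients.  Entries mirror the
# genotypes reported for the evolocumab subgroup plus generic examples of
# each consequence class.
NULL_LDLR_POOL: tuple[VariantRecord, ...] = (
    VariantRecord("LDLR", "c.682G>T", "p.E228X", VariantClass.NONSENSE),
    VariantRecord("LDLR", "c.1672G>T", "p.G558X", VariantClass.NONSENSE),
    VariantRecord("LDLR", "CNV, exon 8-12", None, VariantClass.LARGE_REARRANGEMENT),
    VariantRecord("LDLR", "c.660del", "p.D221Tfs*2", VariantClass.FRAMESHIFT_INDEL),
    VariantRecord("LDLR", "c.664T>C", "p.C222R", VariantClass.MISSENSE),  # LR5 missense
)
DEFECTIVE_LDLR_POOL: tuple[VariantRecord, ...] = (
    VariantRecord("LDLR", "c.519C>G", "p.C173W", VariantClass.MISSENSE),
    VariantRecord("LDLR", "c.1567G>A", "p.V523M", VariantClass.MISSENSE),
    VariantRecord("LDLR", "c.-136C>T", None, VariantClass.PROMOTER_REGULATORY),
)
APOB_PCSK9_POOL: tuple[VariantRecord, ...] = (
    VariantRecord("APOB", "c.10580G>A", "p.R3527Q", VariantClass.MISSENSE),
    VariantRecord("PCSK9", "c.1120G>T", "p.D374Y", VariantClass.MISSENSE),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic registry; defaults follow the published cohort.

    ``response_noise_sd`` is the standard deviation of the achieved
    percentage of expected reduction (P, percentage points) around its
    group level; ``snp_effect_on_response`` is the drop in achieved
    *fraction* of expected per unit of the (centred) weighted SNP score.
    ``escalation_policy_bias`` >= 1 multiplies regimen odds by
    bias**(+rank) for PV-positive and bias**(-rank) for PV-negative
    patients across the intensity ranks, reproducing the observation that
    PV carriers end up on more intensive maximal regimens.
    """

    n_patients: int = 83
    group_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS)
    )
    baseline_ldl_median: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_MEDIAN)
    )
    baseline_ldl_log_sd: float = 0.15
    response_factor: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_FACTOR)
    )
    response_noise_sd: float = 30.0
    allele_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ALLELE_FREQS))
    snp_effect_on_response: float = 0.21
    escalation_policy_bias: float = 1.8
    n_evolocumab: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_proportions = {str(PVGroup(k).value): float(v) for k, v in self.group_proportions.items()}
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
            raise ConfigValidationError("group_proportions must sum to 1")
        if any(v < 0 for v in self.group_proportions.values()):
            raise ConfigValidationError("group_proportions must be non-negative")
        if any(m <= 0 for m in self.baseline_ldl_median.values()):
            raise ConfigValidationError("baseline medians must be positive")
        if not all(0 < f < 1 for f in self.allele_freqs.values()):
            raise ConfigValidationError("allele frequencies must lie in (0, 1)")
        if self.n_patients <= 0:
            raise ConfigValidationError("n_patients must be positive")
        if self.escalation_policy_bias <= 0:
            raise ConfigValidationError("escalation_policy_bias must be positive")
        if not 0 <= self.n_evolocumab <= self.n_patients:
            raise ConfigValidationError("n_evolocumab must be in [0, n_patients]")

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        """Load the ``simulation`` section of a YAML config file."""
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        return cls(**(doc or {}).get("simulation", {}))


@dataclass
class SyntheticCohort:
    """The three pipeline input tables plus the generating ground truth."""

    cohort: pd.DataFrame
    variants: pd.DataFrame
    genotypes: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> dict[str, str]:
        """Write cohort/variants/genotypes/truth CSVs; returns the paths."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name in ("cohort", "variants", "genotypes", "truth"):
            path = os.path.join(outdir, f"{name}.csv")
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        return paths


def assign_variants(group: PVGroup | str, rng: np.random.Generator) -> list[VariantRecord]:
    """Draw a variant genotype consistent with a PV-group label.

    PV-negative patients get none; single-variant groups get one
    heterozygous draw from the matching pool; the compound/homozygous
    group gets two distinct heterozygous LDLR variants.
    """
    group = PVGroup(group)
    if group is PVGroup.PV_NEGATIVE:
        return []
    if group is PVGroup.LDLR_NULL:
        return [NULL_LDLR_POOL[rng.integers(len(NULL_LDLR_POOL))]]
    if group is PVGroup.LDLR_DEFECTIVE:
        return [DEFECTIVE_LDLR_POOL[rng.integers(len(DEFECTIVE_LDLR_POOL))]]
    if group is PVGroup.APOB_PCSK9:
        return [APOB_PCSK9_POOL[rng.integers(len(APOB_PCSK9_POOL))]]
    pool = NULL_LDLR_POOL + DEFECTIVE_LDLR_POOL
    i, j = rng.choice(len(pool), size=2, replace=False)
    return [pool[i], pool[j]]


def _regimen_weights(bias: float, pv_positive: bool) -> np.ndarray:
    base = np.array([c for _, _, c in REGIMEN_FREQUENCIES], dtype=float)
    ranks = np.arange(len(REGIMEN_FREQUENCIES), dtype=float)
    ranks -= ranks.mean()
    w = base * bias ** (ranks if pv_positive else -ranks)
    return w / w.sum()


def _pick_agents(eq_doses: np.ndarray, table: ExpectedReductionTable, rng: np.random.Generator):
    """Realise each atorvastatin-equivalent dose as a concrete agent/dose."""
    options: dict[float, list[tuple[str, float]]] = {}
    for agent, doses in table.equivalence.items():
        for dose, eq in doses.items():
            options.setdefault(float(eq), []).append((agent, float(dose)))
    pref = {"atorvastatin": 0.45, "rosuvastatin": 0.35, "simvastatin": 0.15, "pitavastatin": 0.05}
    agents = np.empty(len(eq_doses), dtype=object)
    dose_mg = np.empty(len(eq_doses), dtype=float)
    for i, eq in enumerate(eq_doses):
        opts = options[float(eq)]
        w = np.array([pref.get(a, 0.05) for a, _ in opts])
        k = rng.choice(len(opts), p=w / w.sum())
        agents[i], dose_mg[i] = opts[k]
    return agents, dose_mg


def expected_score_mean(weights: Sequence[SNPWeight], allele_freqs: Mapping[str, float]) -> float:
    """E[S] = sum(beta_i * 2p_i) / sum(beta_i) under independent binomial dosages."""
    betas = np.abs(np.array([w.beta for w in weights]))
    freqs = np.array([allele_freqs[w.rsid] for w in weights])
    return float((betas * 2 * freqs).sum() / betas.sum())


def generate_cohort(
    config: SimulationConfig,
    table: ExpectedReductionTable | None = None,
    weights: Sequence[SNPWeight] | None = None,
) -> SyntheticCohort:
    """Generate a synthetic registry cohort; deterministic for a fixed seed."""
    table = table or ExpectedReductionTable()
    weights = list(weights) if weights is not None else placeholder_weights()
    n = config.n_patients
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, np.random.SeedSequence(config.seed).spawn(len(_STREAMS)))
    }

    groups_avail = list(config.group_proportions)
    props = np.array([config.group_proportions[g] for g in groups_avail])
    groups = rngs["group"].choice(groups_avail, size=n, p=props)
    pv_positive = groups != PVGroup.PV_NEGATIVE.value

    medians = np.array([config.baseline_ldl_median[g] for g in groups])
    pre = np.exp(rngs["baseline"].normal(np.log(medians), config.baseline_ldl_log_sd))

    # regimen: intensity-ranked categorical, biased by PV status
    w_pos = _regimen_weights(config.escalation_policy_bias, True)
    w_neg = _regimen_weights(config.escalation_policy_bias, False)
    reg_idx = np.empty(n, dtype=int)
    k = len(REGIMEN_FREQUENCIES)
    reg_idx[pv_positive] = rngs["regimen"].choice(k, size=int(pv_positive.sum()), p=w_pos)
    reg_idx[~pv_positive] = rngs["regimen"].choice(k, size=int((~pv_positive).sum()), p=w_neg)
    eq_dose = np.array([REGIMEN_FREQUENCIES[i][0] for i in reg_idx])
    ezetimibe = np.array([REGIMEN_FREQUENCIES[i][1] for i in reg_idx])
    expected = np.array(
        [
            table.expected_reduction(
                Regimen(StatinDose("atorvastatin", d), ezetimibe=bool(e))
            )
            for d, e in zip(eq_dose, ezetimibe)
        ]
    )
    agents, dose_mg = _pick_agents(eq_dose, table, rngs["agent"])

    # genotypes and weighted score
    rsids = [w.rsid for w in weights]
    freqs = np.array([config.allele_freqs[r] for r in rsids])
    G = rngs["genotype"].binomial(2, freqs, size=(n, len(rsids))).astype(float)
    betas = np.abs(np.array([w.beta for w in weights]))
    score = G @ betas / betas.sum()
    mu_s = expected_score_mean(weights, config.allele_freqs)

    # response model
    f = np.array([config.response_factor[g] for g in groups])
    eps = rngs["response"].normal(0.0, config.response_noise_sd, size=n)
    achieved = 100.0 * f - 100.0 * config.snp_effect_on_response * (score - mu_s) + eps
    delta = np.minimum(achieved * expected / 100.0, 100.0)
    post = pre * (1.0 - delta / 100.0)

    followup = np.maximum(6, np.rint(np.exp(rngs["followup"].normal(np.log(10.0), 0.35)))).astype(int)

    ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    # evolocumab add-on for the last n_evolocumab patients
    evolocumab = np.zeros(n, dtype=bool)
    pre_evo = np.full(n, np.nan)
    post_evo = np.full(n, np.nan)
    if config.n_evolocumab:
        sel = slice(n - config.n_evolocumab, n)
        evolocumab[sel] = True
        pre_evo[sel] = post[sel]
        eps2 = rngs["response"].normal(0.0, config.response_noise_sd, size=config.n_evolocumab)
        achieved_evo = 100.0 * f[sel] + eps2
        addon = table.expected_reduction_addon(True)
        delta_evo = np.minimum(achieved_evo * addon / 100.0, 100.0)
        post_evo[sel] = pre_evo[sel] * (1.0 - delta_evo / 100.0)

    cohort = pd.DataFrame(
        {
            "patient_id": ids,
            "pre_ldl": np.round(pre, 1),
            "post_ldl": np.round(post, 1),
            "statin_agent": agents,
            "statin_dose_mg": dose_mg,
            "ezetimibe": ezetimibe,
            "evolocumab": evolocumab,
            "pre_evolocumab_ldl": np.round(pre_evo, 1),
            "post_evolocumab_ldl": np.round(post_evo, 1),
            "followup_months": followup,
        }
    )

    var_rows = []
    vr = rngs["variant"]
    for pid, g in zip(ids, groups):
        for v in assign_variants(g, vr):
            var_rows.append(
                {
                    "patient_id": pid,
                    "gene": v.gene,
                    "cdna_hgvs": v.cdna_hgvs,
                    "protein_hgvs": v.protein_hgvs or "",
                    "variant_class": v.variant_class.value,
                    "zygosity": v.zygosity.value,
                }
            )
    variants = pd.DataFrame(
        var_rows,
        columns=["patient_id", "gene", "cdna_hgvs", "protein_hgvs", "variant_class", "zygosity"],
    )

    genotypes = pd.DataFrame({"patient_id": ids} | {r: G[:, j].astype(int) for j, r in enumerate(rsids)})

    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "pv_group": groups,
            "response_factor": f,
            "score": score,
            "achieved_pct_true": achieved,
            "expected_pct": expected,
        }
    )
    return SyntheticCohort(cohort=cohort, variants=variants, genotypes=genotypes, truth=truth)
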