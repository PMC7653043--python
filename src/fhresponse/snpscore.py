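"""Weighted polygenic score over four LDL-C-associated SNPs.

The score is a weighted mean of LDL-C-raising allele dosages:

    S = sum_i(beta_i * g_i) / sum_i(beta_i)

with g_i in {0, 1, 2} the effect-allele dosage and beta_i the per-allele
effect size from East-Asian GWAS, oriented so every beta is positive
(raising-allele convention).  Under this normalised form 0 <= S <= 2.  The
unnormalised sum sum_i(beta_i * g_i) is available via ``normalized=False``;
the two differ only by the constant factor sum(beta), so correlations and
regression R^2/p against any outcome are identical.

Missing dosages are handled by renormalising over the observed SNPs (no
imputation); a patient with all four missing is rejected.

The four default loci are rs651007 (ABO), rs599839 (CELSR2-PSRC1-SORT1),
rs12654264 (HMGCR) and rs2738446 (LDLR).  The weight file shipped with the
package carries clearly-labelled synthetic placeholder betas for testing;
real analyses must supply the published GWAS weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateWeightError, EmptyGenotypeError, WeightMismatchError

DEFAULT_RSIDS = ("rs651007", "rs599839", "rs12654264", "rs2738446")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SNPWeight:
    """One SNP's effect allele and per-allele beta (LDL-C-raising when positive)."""

    rsid: str
    effect_allele: str
    beta: float
    other_allele: str | None = None


@dataclass(frozen=True)
class ScoreResult:
    score: float
    n_used: int


def orient_weights(weights: Sequence[SNPWeight]) -> list[SNPWeight]:
    """Flip negative-beta weights to the raising-allele orientation.

    For a flipped SNP the effect allele becomes the other allele when known
    (strand-complement labelling otherwise) and dosages must be recoded
    g -> 2 - g; :func:`weighted_snp_score` applies that recode internally
    when given raw signed weights, so orientation here is for bookkeeping
    and export.  Idempotent on already-positive sets.
    """
    out = []
    for w in weights:
        if w.beta == 0:
            raise DegenerateWeightError(f"beta == 0 for {w.rsid}; cannot orient")
        if w.beta > 0:
            out.append(w)
            continue
        flipped_allele = w.other_allele or _COMPLEMENT.get(w.effect_allele.upper(), w.effect_allele)
        out.append(
            replace(
                w,
                effect_allele=flipped_allele,
                other_allele=w.effect_allele,
                beta=-w.beta,
            )
        )
    return out


def _validate_dosage(rsid: str, g) -> float | None:
    if g is None:
        return None
    g = float(g)
    if math.isnan(g):
        return None
    if g not in (0.0, 1.0, 2.0):
        raise ValueError(f"dosage for {rsid} must be 0, 1 or 2, got {g}")
    return g


def weighted_snp_score(
    genotype: Mapping[str, float | int | None],
    weights: Sequence[SNPWeight],
    normalized: bool = True,
) -> ScoreResult:
    """Score one patient's dosage vector against a weight set.

    ``genotype`` maps rsID to effect-allele dosage (0/1/2) or None/NaN for
    missing.  Its key set must equal the weight set's rsIDs.  Negative
    betas are handled by internal reorientation (dosage 2-g, |beta|), so
    the score is invariant to allele-coding flips.
    """
    wmap = {w.rsid: w for w in weights}
    if len(wmap) != len(weights):
        raise WeightMismatchError("duplicate rsids in weight set")
    if set(genotype) != set(wmap):
        raise WeightMismatchError(
            f"genotype rsids {sorted(genotype)} do not match weight rsids {sorted(wmap)}"
        )
    num = 0.0
    den = 0.0
    n_used = 0
    for rsid, w in wmap.items():
        if w.beta == 0:
            raise DegenerateWeightError(f"beta == 0 for {rsid}")
        g = _validate_dosage(rsid, genotype[rsid])
        if g is None:
            continue
        beta, dose = (w.beta, g) if w.beta > 0 else (-w.beta, 2.0 - g)
        num += beta * dose
        den += beta
        n_used += 1
    if n_used == 0:
        raise EmptyGenotypeError("all SNP dosages are missing")
    return ScoreResult(score=num / den if normalized else num, n_used=n_used)


def score_table(
    genotypes: pd.DataFrame,
    weights: Sequence[SNPWeight],
    normalized: bool = True,
    id_column: str = "patient_id",
) -> pd.DataFrame:
    """Score every patient in a genotype table (one dosage column per rsID).

    Patients with all dosages missing are excluded from the output (no
    imputation); callers detect them by comparing patient_id sets.
    Returns a frame with columns ``patient_id, score, n_used``.
    """
    rsids = [w.rsid for w in weights]
    missing_cols = [r for r in rsids if r not in genotypes.columns]
    if missing_cols:
        raise WeightMismatchError(f"genotype table lacks dosage columns: {missing_cols}")
    G = genotypes[rsids].to_numpy(dtype=float)
    if np.nanmin(G, initial=0) < 0 or np.nanmax(G, initial=0) > 2:
        raise ValueError("dosages must lie in [0, 2]")
    betas = np.array([w.beta for w in weights], dtype=float)
    if np.any(betas == 0):
        raise DegenerateWeightError("beta == 0 in weight set")
    # reorient negative betas: dosage 2-g, |beta|
    flip = betas < 0
    G = np.where(flip[None, :], 2.0 - G, G)
    betas = np.abs(betas)
    obs = ~np.isnan(G)
    num = np.nansum(G * betas[None, :], axis=1)
    den = (obs * betas[None, :]).sum(axis=1)
    n_used = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = num / den if normalized else num
    out = pd.DataFrame(
        {
            id_column: genotypes[id_column].to_numpy(),
            "score": score,
            "n_used": n_used,
        }
    )
    return out[out["n_used"] > 0].reset_index(drop=True)


def placeholder_weights() -> list[SNPWeight]:
    """The packaged synthetic placeholder weight set (testing only).

    The betas are invented stand-ins at a plausible per-allele magnitude;
    substantive analyses must load the published GWAS weights instead.
    """
    from importlib.resources import files

    with files("fhresponse.data").joinpath("snp_weights_synthetic.csv").open("r") as fh:
        return load_weights(fh)


def load_weights(path) -> list[SNPWeight]:
    """Read a weight file (CSV: rsid, effect_allele, beta[, other_allele])."""
    df = pd.read_csv(path, comment="#")
    required = {"rsid", "effect_allele", "beta"}
    if not required.issubset(df.columns):
        raise WeightMismatchError(f"weight file must have columns {sorted(required)}")
    return [
        SNPWeight(
            rsid=str(r.rsid),
            effect_allele=str(r.effect_allele),
            beta=float(r.beta),
            other_allele=(str(r.other_allele) if "other_allele" in df.columns and pd.notna(r.other_allele) else None),
        )
        for r in df.itertuples()
    ]
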