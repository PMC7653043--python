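"""Expected LDL-C reduction for statin/ezetimibe/evolocumab regimens.

The efficacy model is a dose-equivalence lookup, not a pharmacokinetic
model.  Every statin dose is first converted to its atorvastatin-equivalent
daily dose (one of 10/20/40/80 mg) using a standard potency ladder; the
regimen — equivalent dose with or without ezetimibe 10 mg/day — then maps
to an expected percent LDL-C reduction ``E`` taken from trial-derived
efficacy tables.  Evolocumab 140 mg every 2 weeks carries an *additional*
expected reduction applied to the LDL-C achieved on the background
statin/ezetimibe regimen, so it is handled by a separate add-on lookup.

Sign convention: efficacy tables in the literature print reductions as
negative percent changes; this module stores ``E`` as a positive magnitude
throughout.

Agents or doses absent from the tables raise rather than guess; both the
equivalence ladder and the efficacy entries are overridable via YAML
config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from numbers import Real
from typing import Mapping

import yaml

from .errors import NotApplicableError, UnmappedAgentError, UnmappedRegimenError

logger = logging.getLogger(__name__)

#: Potency ladder: agent -> {daily dose mg -> atorvastatin-equivalent mg}.
#: Only the moderate-intensity pairing (rosuvastatin 5-10 ~ atorvastatin
#: 10-20) is pinned by the escalation protocol; the remaining rungs follow
#: standard intensity classifications and are config-overridable.
DEFAULT_EQUIVALENCE: dict[str, dict[float, float]] = {
    "atorvastatin": {10.0: 10.0, 20.0: 20.0, 40.0: 40.0, 80.0: 80.0},
    "rosuvastatin": {5.0: 10.0, 10.0: 20.0, 20.0: 40.0, 40.0: 80.0},
    "simvastatin": {20.0: 10.0, 40.0: 20.0, 80.0: 40.0},
    "pitavastatin": {2.0: 10.0, 4.0: 20.0},
}

#: Atorvastatin-equivalent dose (mg/day) -> expected % LDL-C reduction.
DEFAULT_STATIN_ONLY: dict[float, float] = {10.0: 40.0, 20.0: 46.0, 40.0: 52.0, 80.0: 56.0}

#: Same, with ezetimibe 10 mg/day added.  The 80 mg entry is not published
#: in the source efficacy tables; the default extrapolates the ~14-point
#: ezetimibe increment seen between the 40 mg rows (52 -> 66) and is
#: flagged in the log whenever used.
DEFAULT_WITH_EZETIMIBE: dict[float, float] = {20.0: 61.0, 40.0: 66.0, 80.0: 70.0}
EXTRAPOLATED_EZETIMIBE_DOSES: frozenset[float] = frozenset({80.0})

DEFAULT_EVOLOCUMAB_ADDON: float = 54.0


@dataclass(frozen=True)
class StatinDose:
    """A statin agent at a positive daily dose in mg."""

    agent: str
    daily_dose_mg: float

    def __post_init__(self) -> None:
        if not isinstance(self.daily_dose_mg, Real) or not self.daily_dose_mg > 0:
            raise ValueError(f"daily_dose_mg must be > 0, got {self.daily_dose_mg!r}")
        object.__setattr__(self, "agent", str(self.agent).strip().lower())


@dataclass(frozen=True)
class Regimen:
    """A lipid-lowering regimen: optional statin, ezetimibe and evolocumab flags.

    ``ezetimibe=True`` means ezetimibe 10 mg/day; ``evolocumab=True`` means
    evolocumab 140 mg/2 weeks, whose expected effect is additional to the
    background regimen and is only consumed by :func:`expected_reduction_addon`.
    """

    statin: StatinDose | None = None
    ezetimibe: bool = False
    evolocumab: bool = False

    def __post_init__(self) -> None:
        if self.statin is None and not self.ezetimibe and not self.evolocumab:
            raise ValueError("a Regimen must contain at least one component")


def _as_key(dose: float) -> float:
    return float(dose)


@dataclass(frozen=True)
class ExpectedReductionTable:
    """Lookup tables mapping regimens to expected % LDL-C reduction.

    Attributes
    ----------
    equivalence
        agent -> {daily dose mg -> atorvastatin-equivalent dose mg}.
    statin_only, with_ezetimibe
        atorvastatin-equivalent dose mg -> E (%), positive magnitudes.
    evolocumab_addon
        Additional expected % reduction for evolocumab 140 mg/2 weeks,
        relative to the pre-evolocumab LDL-C on background therapy.
    extrapolated_ezetimibe_doses
        Equivalent doses whose with-ezetimibe entry is an extrapolation
        rather than a published value; logged when resolved.
    """

    equivalence: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: {a: dict(d) for a, d in DEFAULT_EQUIVALENCE.items()}
    )
    statin_only: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_STATIN_ONLY))
    with_ezetimibe: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_WITH_EZETIMIBE)
    )
    evolocumab_addon: float = DEFAULT_EVOLOCUMAB_ADDON
    extrapolated_ezetimibe_doses: frozenset[float] = EXTRAPOLATED_EZETIMIBE_DOSES

    # -- lookups ---------------------------------------------------------

    def atorvastatin_equivalent(self, statin: StatinDose) -> float:
        """Convert a statin dose to its atorvastatin-equivalent daily dose.

        Raises :class:`UnmappedAgentError` for agents or doses outside the
        ladder (intermediate doses are rejected, not interpolated).
        """
        agent = statin.agent
        if agent not in self.equivalence:
            raise UnmappedAgentError(f"statin agent not in equivalence table: {agent!r}")
        doses = self.equivalence[agent]
        key = _as_key(statin.daily_dose_mg)
        for dose, equiv in doses.items():
            if _as_key(dose) == key:
                return float(equiv)
        raise UnmappedAgentError(
            f"dose {statin.daily_dose_mg} mg of {agent!r} not in equivalence table "
            f"(known doses: {sorted(float(d) for d in doses)})"
        )

    def expected_reduction(self, regimen: Regimen) -> float:
        """Expected % LDL-C reduction ``E`` for a statin +/- ezetimibe regimen.

        ``regimen.evolocumab`` must be False here; the evolocumab add-on is
        resolved by :meth:`expected_reduction_addon` against the
        pre-evolocumab baseline instead.
        """
        if regimen.evolocumab:
            raise UnmappedRegimenError(
                "evolocumab is an add-on; use expected_reduction_addon with the "
                "pre-evolocumab baseline"
            )
        if regimen.statin is None:
            raise UnmappedRegimenError(
                "no efficacy entry for ezetimibe monotherapy; a statin is required"
            )
        equiv = self.atorvastatin_equivalent(regimen.statin)
        table = self.with_ezetimibe if regimen.ezetimibe else self.statin_only
        for dose, e in table.items():
            if _as_key(dose) == equiv:
                if regimen.ezetimibe and equiv in self.extrapolated_ezetimibe_doses:
                    logger.warning(
                        "expected reduction for atorvastatin-equivalent %g mg + "
                        "ezetimibe uses the extrapolated entry E=%g%%",
                        equiv,
                        e,
                    )
                return float(e)
        raise UnmappedRegimenError(
            f"no expected-reduction entry for atorvastatin-equivalent {equiv:g} mg "
            f"(ezetimibe={regimen.ezetimibe})"
        )

    def expected_reduction_addon(self, evolocumab: bool = True) -> float:
        """Additional expected % reduction for the evolocumab add-on."""
        if not evolocumab:
            raise NotApplicableError("evolocumab add-on requested for a regimen without it")
        return float(self.evolocumab_addon)

    # -- config round-trip ----------------------------------------------

    def to_yaml(self, path=None) -> str:
        """Serialize to YAML (sections: equivalence, expected_reduction, evolocumab)."""
        doc = {
            "equivalence": {
                agent: {float(d): float(e) for d, e in doses.items()}
                for agent, doses in self.equivalence.items()
            },
            "expected_reduction": {
                "statin_only": {float(d): float(e) for d, e in self.statin_only.items()},
                "with_ezetimibe": {float(d): float(e) for d, e in self.with_ezetimibe.items()},
                "extrapolated_ezetimibe_doses": sorted(
                    float(d) for d in self.extrapolated_ezetimibe_doses
                ),
            },
            "evolocumab": {"addon": float(self.evolocumab_addon)},
        }
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExpectedReductionTable":
        """Load from a YAML string or file path produced by :meth:`to_yaml`.

        Missing sections fall back to the defaults, so a config may override
        only the evolocumab add-on, say.
        """
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" not in text and not text.lstrip().startswith("{"):
                with open(text) as fh:
                    doc = yaml.safe_load(fh)
            else:
                doc = yaml.safe_load(text)
        doc = doc or {}
        default = cls()
        er = doc.get("expected_reduction", {})
        return cls(
            equivalence={
                str(a): {float(d): float(e) for d, e in doses.items()}
                for a, doses in doc.get("equivalence", default.equivalence).items()
            },
            statin_only={float(d): float(e) for d, e in er.get("statin_only", default.statin_only).items()},
            with_ezetimibe={
                float(d): float(e)
                for d, e in er.get("with_ezetimibe", default.with_ezetimibe).items()
            },
            evolocumab_addon=float(
                doc.get("evolocumab", {}).get("addon", default.evolocumab_addon)
            ),
            extrapolated_ezetimibe_doses=frozenset(
                float(d)
                for d in er.get(
                    "extrapolated_ezetimibe_doses", default.extrapolated_ezetimibe_doses
                )
            ),
        )

    def with_addon(self, addon: float) -> "ExpectedReductionTable":
        return replace(self, evolocumab_addon=float(addon))


# Module-level conveniences mirroring the table methods ------------------

def atorvastatin_equivalent(
    statin: StatinDose, table: ExpectedReductionTable | None = None
) -> float:
    return (table or ExpectedReductionTable()).atorvastatin_equivalent(statin)


def expected_reduction(regimen: Regimen, table: ExpectedReductionTable | None = None) -> float:
    return (table or ExpectedReductionTable()).expected_reduction(regimen)


def expected_reduction_addon(
    evolocumab: bool = True, table: ExpectedReductionTable | None = None
) -> float:
    return (table or ExpectedReductionTable()).expected_reduction_addon(evolocumab)
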