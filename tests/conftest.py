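import pandas as pd
import pytest
from hypothesis import settings

from fhresponse.regimen import ExpectedReductionTable

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_table() -> ExpectedReductionTable:
    return ExpectedReductionTable()


#: The seven evolocumab-treated patients: one PV-negative plus six carriers
#: (two with the same nonsense variant, one exon-level CNV, one defective
#: missense, and two compound/homozygous genotypes).  Pre/post values are
#: the LDL-C on the background regimen immediately before evolocumab and
#: after >= 3 months of the add-on.
EVOLOCUMAB_PATIENTS = [
    # (patient_id, pre_evo, post_evo, variants)
    ("EV1", 157, 27, []),
    ("EV2", 169, 149, [("LDLR", "c.682G>T", "p.E228X", "nonsense", "heterozygous")]),
    ("EV3", 126, 99, [("LDLR", "c.682G>T", "p.E228X", "nonsense", "heterozygous")]),
    ("EV4", 138, 107, [("LDLR", "CNV, exon 8-12", "", "large_rearrangement", "heterozygous")]),
    ("EV5", 138, 33, [("LDLR", "c.519C>G", "p.C173W", "missense", "heterozygous")]),
    (
        "EV6",
        410,
        329,
        [
            ("LDLR", "c.1672G>T", "p.G558X", "nonsense", "heterozygous"),
            ("LDLR", "c.-136C>T", "", "promoter_regulatory", "heterozygous"),
        ],
    ),
    (
        "EV7",
        299,
        70,
        [
            ("LDLR", "c.1567G>A", "p.V523M", "missense", "heterozygous"),
            ("LDLR", "c.-136C>T", "", "promoter_regulatory", "heterozygous"),
        ],
    ),
]


@pytest.fixture(scope="session")
def evolocumab_cohort() -> pd.DataFrame:
    rows = []
    for pid, pre_evo, post_evo, _ in EVOLOCUMAB_PATIENTS:
        rows.append(
            {
                "patient_id": pid,
                "pre_ldl": 320.0,  # pre-statin baseline (background phase)
                "post_ldl": float(pre_evo),
                "statin_agent": "atorvastatin",
                "statin_dose_mg": 40,
                "ezetimibe": True,
                "evolocumab": True,
                "pre_evolocumab_ldl": float(pre_evo),
                "post_evolocumab_ldl": float(post_evo),
                "followup_months": 12,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def evolocumab_variants() -> pd.DataFrame:
    rows = []
    for pid, _, _, variants in EVOLOCUMAB_PATIENTS:
        for gene, cdna, prot, vclass, zyg in variants:
            rows.append(
                {
                    "patient_id": pid,
                    "gene": gene,
                    "cdna_hgvs": cdna,
                    "protein_hgvs": prot,
                    "variant_class": vclass,
                    "zygosity": zyg,
                }
            )
    return pd.DataFrame(rows)
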