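"""Diagnosis codes and the LPD / MPD grouping used throughout the package.

Malignant blood disorders (MBD) are grouped into lymphoproliferative
disorders (LPD: lymphoid leukemias, lymphomas, myeloma, MGUS),
myeloproliferative disorders (MPD: myeloid leukemias and related) and a
residual OTHER group (leukemia NOS, malignant histiocytosis).  Chronic
lymphocytic leukemia (CLL) is singled out because its transgenerational
segregation differs from every other diagnosis.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass


class LineageGroup(str, enum.Enum):
    LPD = "LPD"
    MPD = "MPD"
    OTHER = "OTHER"


#: label -> (canonical ICD-10 code, group)
DEFAULT_GROUPS: dict[str, tuple[str, LineageGroup]] = {
    "CLL": ("C91.1", LineageGroup.LPD),
    "ALL": ("C91.0", LineageGroup.LPD),
    "other-leukemia": ("C91.9", LineageGroup.LPD),
    "MM": ("C90", LineageGroup.LPD),
    "MGUS": ("D47.2", LineageGroup.LPD),
    "HL": ("C81.1", LineageGroup.LPD),
    "DLBCL": ("C83.3", LineageGroup.LPD),
    "FL": ("C82", LineageGroup.LPD),
    "other-lymphoma": ("C85", LineageGroup.LPD),
    "AML": ("C92.0", LineageGroup.MPD),
    "CML": ("C92.1", LineageGroup.MPD),
    "other-MPD": ("D47.1", LineageGroup.MPD),
    "L-NOS": ("C95.9", LineageGroup.OTHER),
    "MH": ("C96.1", LineageGroup.OTHER),
}

#: ICD-10 code -> label, for the codes the default mapping knows about.
_CODE_TO_LABEL: dict[str, str] = {code: label for label, (code, _) in DEFAULT_GROUPS.items()}
# common synonym spellings seen in registry extracts
_CODE_TO_LABEL.update({"C91": "other-leukemia", "C83": "DLBCL", "C85.9": "other-lymphoma",
                       "C90.0": "MM", "C81": "HL", "C92.2": "AML"})


@dataclass(frozen=True)
class DiagnosisCode:
    """One diagnosis: ICD-10 code, short label, and its LPD/MPD group."""

    icd10: str
    label: str
    lineage_group: LineageGroup

    @property
    def is_cll(self) -> bool:
        return self.label == "CLL"

    @classmethod
    def from_label(cls, label: str) -> "DiagnosisCode":
        if label not in DEFAULT_GROUPS:
            raise KeyError(f"unknown diagnosis label: {label!r}")
        code, group = DEFAULT_GROUPS[label]
        return cls(icd10=code, label=label, lineage_group=group)

    @classmethod
    def from_icd10(cls, icd10: str,
                   mapping: dict[str, str] | None = None) -> "DiagnosisCode":
        """Resolve an ICD-10 code to a labelled, grouped diagnosis.

        ``mapping`` overrides/extends the default code->label table; unknown
        codes fall back to a coarse group guess: C81-C86 lymphoma, C90-C91
        lymphoid, C92-C94/D45-D47 myeloid, otherwise OTHER.
        """
        table = dict(_CODE_TO_LABEL)
        if mapping:
            table.update(mapping)
        code = icd10.strip()
        if code in table:
            return cls.from_label(table[code])
        root = code.split(".")[0]
        if root in table:
            return cls.from_label(table[root])
        # coarse fallback by ICD-10 block
        if root.startswith("C8"):
            return cls(icd10=code, label="other-lymphoma", lineage_group=LineageGroup.LPD)
        if root in ("C90", "C91"):
            return cls(icd10=code, label="other-leukemia", lineage_group=LineageGroup.LPD)
        if root in ("C92", "C93", "C94", "D45", "D46", "D47"):
            return cls(icd10=code, label="other-MPD", lineage_group=LineageGroup.MPD)
        return cls(icd10=code, label="L-NOS", lineage_group=LineageGroup.OTHER)
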