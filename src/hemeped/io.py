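"""Reading and writing pedigrees: CSV dialect and 6-column PED + sidecar.

CSV dialect: UTF-8, comma-separated, header
``id,father_id,mother_id,sex,birth_order,birth_year,affected,icd10,onset_age``
with the empty string for missing values.  An optional ``uncertain`` column
marks members whose position in the family tree is unreliable; they are
excluded on read (and parent references to them are severed, turning their
children into founders).

PED: standard whitespace-separated ``FID IID PAT MAT SEX PHENO`` with
SEX 1=male/2=female and PHENO 2=affected/1=unaffected/0 or -9 missing.  PED's
single phenotype column cannot carry a diagnosis or an onset age, so a CSV
sidecar keyed by IID supplies ``icd10, onset_age, birth_order, birth_year``.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import pandas as pd

from .diagnoses import DiagnosisCode
from .errors import ValidationError
from .pedigree import Individual, KindredMode, Pedigree, Sex

CSV_COLUMNS = ["id", "father_id", "mother_id", "sex", "birth_order",
               "birth_year", "affected", "icd10", "onset_age"]

def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and v != v):  # None or NaN
        return None
    s = str(v).strip()
    return s or None


def _opt_int(v) -> Optional[int]:
    s = _opt_str(v)
    return int(float(s)) if s is not None else None


def _opt_float(v) -> Optional[float]:
    s = _opt_str(v)
    return float(s) if s is not None else None


def read_pedigree(path, format: str = "csv", *, sidecar=None, family_id: str | None = None,
                  kindred_mode: KindredMode = KindredMode.NUCLEAR,
                  icd10_mapping: dict | None = None) -> Pedigree:
    """Read and validate a pedigree from ``path``.

    Parameters
    ----------
    format : {"csv", "ped"}
    sidecar : path, required for ``ped``
        CSV keyed by individual id carrying icd10/onset_age/birth_order/birth_year.
    icd10_mapping : dict, optional
        Extra ICD-10 code -> label entries overriding the default grouping.
    """
    path = Path(path)
    if format == "csv":
        ped = _read_csv(path, family_id=family_id, kindred_mode=kindred_mode,
                        icd10_mapping=icd10_mapping)
    elif format == "ped":
        if sidecar is None:
            raise ValueError("PED format requires a phenotype sidecar path")
        ped = _read_ped(path, Path(sidecar), family_id=family_id,
                        kindred_mode=kindred_mode, icd10_mapping=icd10_mapping)
    else:
        raise ValueError(f"unknown format: {format!r}")
    return ped.with_derived_birth_orders()


def write_pedigree(p: Pedigree, path, format: str = "csv", *, sidecar=None) -> None:
    """Write ``p`` so that a subsequent read reproduces it field-for-field."""
    path = Path(path)
    if format == "csv":
        _write_csv(p, path)
    elif format == "ped":
        if sidecar is None:
            raise ValueError("PED format requires a phenotype sidecar path")
        _write_ped(p, path, Path(sidecar))
    else:
        raise ValueError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
def _parse_bool(v, row_id) -> bool:
    s = str(v).strip().lower()
    if s in {"1", "true", "yes"}:
        return True
    if s in {"0", "false", "no", ""}:
        return False
    raise ValidationError(f"row {row_id!r}: cannot parse affected flag {v!r}")


def _make_individual(rec: dict, icd10_mapping) -> Individual:
    affected = _parse_bool(rec.get("affected", ""), rec["id"])
    icd10 = _opt_str(rec.get("icd10"))
    if affected and icd10 is None:
        raise ValidationError(f"affected individual {rec['id']!r} has no diagnosis")
    if not affected and icd10 is not None:
        raise ValidationError(f"unaffected individual {rec['id']!r} carries a diagnosis")
    sex_raw = str(rec.get("sex", "")).strip().lower()
    if sex_raw in {"male", "m", "1"}:
        sex = Sex.MALE
    elif sex_raw in {"female", "f", "2"}:
        sex = Sex.FEMALE
    else:
        raise ValidationError(f"individual {rec['id']!r}: unknown sex {rec.get('sex')!r}")
    return Individual(
        id=str(rec["id"]).strip(),
        father_id=_opt_str(rec.get("father_id")),
        mother_id=_opt_str(rec.get("mother_id")),
        sex=sex,
        birth_order=_opt_int(rec.get("birth_order")),
        birth_year=_opt_int(rec.get("birth_year")),
        affected=affected,
        diagnosis=DiagnosisCode.from_icd10(icd10, icd10_mapping) if icd10 else None,
        onset_age=_opt_float(rec.get("onset_age")),
    )


def _drop_uncertain(records: list[dict]) -> list[dict]:
    uncertain = {str(r["id"]).strip() for r in records
                 if str(r.get("uncertain", "")).strip().lower() in {"1", "true", "yes"}}
    if not uncertain:
        return records
    kept = []
    for r in records:
        rid = str(r["id"]).strip()
        if rid in uncertain:
            continue
        for col in ("father_id", "mother_id"):
            if _opt_str(r.get(col)) in uncertain:
                r = dict(r)
                r[col] = ""
        kept.append(r)
    return kept


def _read_csv(path: Path, *, family_id, kindred_mode, icd10_mapping) -> Pedigree:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValidationError(f"{path}: empty pedigree file")
    rows = _drop_uncertain(rows)
    inds = [_make_individual(r, icd10_mapping) for r in rows]
    return Pedigree(inds, family_id=family_id or path.stem, kindred_mode=kindred_mode)


def _write_csv(p: Pedigree, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for ind in p:
            w.writerow([
                ind.id,
                ind.father_id or "",
                ind.mother_id or "",
                ind.sex.value,
                "" if ind.birth_order is None else ind.birth_order,
                "" if ind.birth_year is None else ind.birth_year,
                int(ind.affected),
                ind.diagnosis.icd10 if ind.diagnosis else "",
                "" if ind.onset_age is None else repr(ind.onset_age),
            ])


def _read_ped(path: Path, sidecar: Path, *, family_id, kindred_mode, icd10_mapping) -> Pedigree:
    # dtype=str: numeric conversion stays with our own parsers so floats
    # round-trip bit-exactly
    side = pd.read_csv(sidecar, dtype=str).set_index("id") \
        if sidecar.exists() else pd.DataFrame()
    inds = []
    fid_seen = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 6:
                raise ValidationError(f"{path}: malformed PED line: {line.rstrip()!r}")
            fid, iid, pat, mat, sex, pheno = parts[:6]
            fid_seen = fid_seen or fid
            extra = side.loc[iid].to_dict() if iid in side.index else {}
            affected = pheno.strip() == "2"
            inds.append(_make_individual({
                "id": iid,
                "father_id": "" if pat in {"0", "-9"} else pat,
                "mother_id": "" if mat in {"0", "-9"} else mat,
                "sex": sex,
                "affected": "1" if affected else "0",
                "icd10": extra.get("icd10", ""),
                "onset_age": extra.get("onset_age", ""),
                "birth_order": extra.get("birth_order", ""),
                "birth_year": extra.get("birth_year", ""),
            }, icd10_mapping))
    if not inds:
        raise ValidationError(f"{path}: empty pedigree file")
    return Pedigree(inds, family_id=family_id or fid_seen or path.stem,
                    kindred_mode=kindred_mode)


def _write_ped(p: Pedigree, path: Path, sidecar: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ind in p:
            fh.write(" ".join([
                p.family_id, ind.id,
                ind.father_id or "0", ind.mother_id or "0",
                "1" if ind.sex is Sex.MALE else "2",
                "2" if ind.affected else "1",
            ]) + "\n")
    with open(sidecar, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "icd10", "onset_age", "birth_order", "birth_year"])
        for ind in p:
            w.writerow([
                ind.id,
                ind.diagnosis.icd10 if ind.diagnosis else "",
                "" if ind.onset_age is None else repr(ind.onset_age),
                "" if ind.birth_order is None else ind.birth_order,
                "" if ind.birth_year is None else ind.birth_year,
            ])
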