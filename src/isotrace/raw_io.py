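"""Reading and writing of external artifacts.

This module owns every file format the pipeline touches — centroided MS1
raw runs (mzML/mzXML), metabolite annotation tables, untargeted feature
tables from prior peak detection of the unlabeled samples, and the final
mass-isotopomer-distribution (MID) table — plus the extracted-ion-
chromatogram (EIC) primitive every downstream stage is built on.

Retention time is seconds everywhere in this package; kinetics converts
to hours at its own boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mzxml as _mzxml

logger = logging.getLogger("isotrace")

# m/z tolerance rule for EIC extraction: fixed 0.01 Da below 400 Da,
# 25 ppm above.
MZ_TOL_PPM = 25.0
MZ_TOL_DA_LOW_MASS = 0.01
MZ_TOL_SWITCH_DA = 400.0

#: Adducts accepted as reliable; value = (m/z shift from the neutral
#: monoisotopic mass, polarity).  Shifts include the electron mass, so
#: mz = M_neutral + shift for the singly charged ion.
_ELECTRON = 0.00054857990907
_PROTON = 1.00727646688  # H (1.00782503207) minus electron
ADDUCT_SHIFTS: dict[str, tuple[float, str]] = {
    "[M+H]+": (_PROTON, "positive"),
    "[M+Na]+": (22.98976928 - _ELECTRON, "positive"),
    "[M+NH4]+": (18.03437413 - _ELECTRON, "positive"),
    "[M-H]-": (-_PROTON, "negative"),
    "[M+Cl]-": (34.96885268 + _ELECTRON, "negative"),
    "[M-H-H2O]-": (-_PROTON - 18.01056468, "negative"),
}


def normalize_adduct(adduct: str) -> str:
    """Map unicode minus signs and stray spaces onto the canonical form."""
    return (
        adduct.replace("−", "-")
        .replace("–", "-")
        .replace(" ", "")
    )


class FormatError(ValueError):
    """Raised for malformed or unreadable input files."""


class SchemaError(ValueError):
    """Raised when a delimited table lacks required columns."""


class ValidationError(ValueError):
    """Raised when record fields violate their invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Scan:
    rt: float  # seconds
    mz: np.ndarray  # Da, ascending
    intensity: np.ndarray  # counts, >= 0


@dataclass
class RawRun:
    """All MS1 scans of one LC–MS run, in retention-time order."""

    run_id: str
    polarity: str  # "positive" | "negative"
    scans: list[Scan] = field(default_factory=list)

    @property
    def rt(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    def validate(self) -> None:
        rts = self.rt
        if len(rts) > 1 and not np.all(np.diff(rts) > 0):
            raise ValidationError(f"run {self.run_id}: scan RTs not strictly increasing")
        for s in self.scans:
            if len(s.mz) > 1 and not np.all(np.diff(s.mz) >= 0):
                raise ValidationError(f"run {self.run_id}: mz array not sorted at rt={s.rt}")
            if np.any(s.intensity < 0):
                raise ValidationError(f"run {self.run_id}: negative intensity at rt={s.rt}")


@dataclass(frozen=True)
class AnnotationRecord:
    metabolite_id: str
    name: str
    formula: str
    adduct: str
    mz: float
    rt: float  # seconds
    msi_level: int
    feature_id: str


@dataclass
class FeatureRecord:
    feature_id: str
    mz: float
    rt_apex: float
    rt_min: float
    rt_max: float
    per_sample_height: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.rt_min < self.rt_apex < self.rt_max):
            raise ValidationError(
                f"feature {self.feature_id}: require rt_min < rt_apex < rt_max, "
                f"got ({self.rt_min}, {self.rt_apex}, {self.rt_max})"
            )


@dataclass
class EIC:
    """Intensity-vs-RT trace for one narrow m/z window in one run."""

    mz_center: float
    mz_tol: float
    rt: np.ndarray  # seconds
    intensity: np.ndarray  # counts
    run_id: str = ""

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValidationError("EIC rt and intensity must have equal length")

    def __len__(self) -> int:
        return len(self.rt)


# ---------------------------------------------------------------------------
# Raw-run reading
# ---------------------------------------------------------------------------

def read_raw_run(path: str, run_id: str | None = None) -> RawRun:
    """Read the MS1 scans of an mzML or mzXML file.

    MS2 (and higher) scans are skipped.  Profile-mode spectra are rejected:
    the pipeline assumes centroided data.
    """
    if run_id is None:
        run_id = os.path.splitext(os.path.basename(path))[0]
    lower = path.lower()
    try:
        if lower.endswith(".mzxml"):
            scans, polarity = _read_mzxml(path)
        else:
            scans, polarity = _read_mzml(path)
    except (OSError, FormatError):
        raise
    except Exception as exc:  # lxml / pyteomics parse failures
        raise FormatError(f"cannot parse {path!r}: {exc}") from exc
    if not scans:
        raise FormatError(f"{path!r} contains no MS1 scans")
    scans.sort(key=lambda s: s.rt)
    run = RawRun(run_id=run_id, polarity=polarity, scans=scans)
    run.validate()
    return run


def _read_mzml(path: str) -> tuple[list[Scan], str]:
    """Stream the MS1 spectra of an mzML file.

    Implemented directly on lxml (cvParam accessions drive the decoding):
    handles 32/64-bit float binary arrays, uncompressed or zlib, and scan
    start times in seconds or minutes.
    """
    import base64
    import zlib as _zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    scans: list[Scan] = []
    polarity = "positive"
    if os.path.getsize(path) == 0:
        raise FormatError(f"{path!r} is empty")
    for _, elem in etree.iterparse(path, tag=f"{ns}spectrum"):
        accessions = {
            cv.get("accession"): cv.get("value")
            for cv in elem.iter(f"{ns}cvParam")
        }
        ms_level = int(accessions.get("MS:1000511", "1"))
        if ms_level != 1:
            elem.clear()
            continue
        if "MS:1000128" in accessions:  # profile spectrum
            raise FormatError(
                f"{path!r}: profile-mode spectrum {elem.get('id')!r}; centroided data required"
            )
        if "MS:1000129" in accessions:
            polarity = "negative"

        rt = None
        for scan_el in elem.iter(f"{ns}scan"):
            for cv in scan_el.iter(f"{ns}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    unit = (cv.get("unitName") or "minute").lower()
                    if "min" in unit:
                        rt *= 60.0
        if rt is None:
            raise FormatError(f"{path!r}: spectrum {elem.get('id')!r} lacks a scan start time")

        arrays: dict[str, np.ndarray] = {}
        for bda in elem.iter(f"{ns}binaryDataArray"):
            acc = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
            binary = bda.find(f"{ns}binary")
            raw = base64.b64decode(binary.text or "")
            if "MS:1000574" in acc:  # zlib
                raw = _zlib.decompress(raw)
            dtype = "<f4" if "MS:1000521" in acc else "<f8"
            data = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in acc:
                arrays["mz"] = data
            elif "MS:1000515" in acc:
                arrays["intensity"] = data
        if "mz" not in arrays or "intensity" not in arrays:
            raise FormatError(
                f"{path!r}: spectrum {elem.get('id')!r} missing m/z or intensity array"
            )
        order = np.argsort(arrays["mz"], kind="stable")
        scans.append(Scan(rt=rt, mz=arrays["mz"][order], intensity=arrays["intensity"][order]))
        elem.clear()
    return scans, polarity


def _read_mzxml(path: str) -> tuple[list[Scan], str]:
    scans: list[Scan] = []
    polarity = "positive"
    with _mzxml.MzXML(path) as reader:
        for spec in reader:
            if int(spec.get("msLevel", 1)) != 1:
                continue
            if spec.get("centroided") in (False, 0, "0"):
                raise FormatError(f"{path!r}: profile-mode scan; centroided data required")
            if spec.get("polarity") == "-":
                polarity = "negative"
            rt = float(spec["retentionTime"]) * 60.0  # pyteomics returns minutes
            mz = np.asarray(spec["m/z array"], dtype=float)
            inten = np.asarray(spec["intensity array"], dtype=float)
            order = np.argsort(mz, kind="stable")
            scans.append(Scan(rt=rt, mz=mz[order], intensity=inten[order]))
    return scans, polarity


# ---------------------------------------------------------------------------
# Minimal mzML writing (used by the synthetic-data generator)
# ---------------------------------------------------------------------------

def write_mzml(run: RawRun, path: str) -> None:
    """Write a RawRun as a minimal centroided-MS1 mzML file.

    The output carries just the subset of the schema the reader needs
    (scan times in seconds, 64-bit little-endian uncompressed arrays);
    it round-trips through :func:`read_raw_run`.
    """
    import base64
    import struct

    pol_acc = (
        '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
        if run.polarity == "positive"
        else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>'
    )

    def b64(arr: np.ndarray) -> str:
        raw = struct.pack(f"<{len(arr)}d", *np.asarray(arr, dtype=float))
        return base64.b64encode(raw).decode("ascii")

    parts: list[str] = []
    parts.append('<?xml version="1.0" encoding="utf-8"?>')
    parts.append(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<cvList count="1"><cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/></cvList>'
        f'<run id="{run.run_id}">'
        f'<spectrumList count="{len(run.scans)}">'
    )
    for i, scan in enumerate(run.scans):
        n = len(scan.mz)
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            f"{pol_acc}"
            "<scanList count=\"1\"><scan>"
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>'
            "</scan></scanList>"
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="{len(b64(scan.mz))}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>'
            f"<binary>{b64(scan.mz)}</binary></binaryDataArray>"
            f'<binaryDataArray encodedLength="{len(b64(scan.intensity))}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>'
            f"<binary>{b64(scan.intensity)}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
    parts.append("</spectrumList></run></mzML>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("".join(parts))


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = (
    "metabolite_id", "name", "formula", "adduct", "mz", "rt", "msi_level", "feature_id",
)


def read_annotation_table(path: str) -> list[AnnotationRecord]:
    """Read the metabolite annotation table (CSV/TSV).

    Rows with unparseable formulas or adducts outside the reliable-adduct
    vocabulary are rejected and logged with their row numbers; the
    remaining rows are returned.
    """
    from .targets import FormulaError, parse_formula

    df = _read_table(path)
    missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"annotation table {path!r} missing columns: {sorted(missing)}")
    records: list[AnnotationRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        adduct = normalize_adduct(str(row.adduct))
        if adduct not in ADDUCT_SHIFTS:
            logger.warning("annotation row %d: adduct %r not in reliable-adduct "
                           "vocabulary; row rejected", row_no, row.adduct)
            continue
        try:
            parse_formula(str(row.formula))
        except FormulaError as exc:
            logger.warning("annotation row %d: bad formula %r (%s); row rejected",
                           row_no, row.formula, exc)
            continue
        rec = AnnotationRecord(
            metabolite_id=str(row.metabolite_id),
            name=str(row.name),
            formula=str(row.formula),
            adduct=adduct,
            mz=float(row.mz),
            rt=float(row.rt),
            msi_level=int(row.msi_level),
            feature_id=str(row.feature_id),
        )
        if rec.mz <= 0 or rec.rt < 0:
            raise ValidationError(f"annotation row {row_no}: mz must be >0 and rt >=0")
        records.append(rec)
    return records


def write_annotation_table(records: Iterable[AnnotationRecord], path: str) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = ("feature_id", "mz", "rt_apex", "rt_min", "rt_max")


def read_feature_table(path: str) -> list[FeatureRecord]:
    """Read the untargeted feature table of the unlabeled samples.

    Any column named ``height_<run_id>`` is treated as a per-sample peak
    height.  Duplicate feature ids are an error.
    """
    df = _read_table(path)
    missing = set(_FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"feature table {path!r} missing columns: {sorted(missing)}")
    height_cols = [c for c in df.columns if c.startswith("height_")]
    seen: set[str] = set()
    records: list[FeatureRecord] = []
    for row in df.itertuples(index=False):
        fid = str(row.feature_id)
        if fid in seen:
            raise ValidationError(f"duplicate feature_id {fid!r} in {path!r}")
        seen.add(fid)
        heights = {c[len("height_"):]: float(getattr(row, c)) for c in height_cols}
        records.append(
            FeatureRecord(
                feature_id=fid,
                mz=float(row.mz),
                rt_apex=float(row.rt_apex),
                rt_min=float(row.rt_min),
                rt_max=float(row.rt_max),
                per_sample_height=heights,
            )
        )
    return records


def write_feature_table(records: Iterable[FeatureRecord], path: str) -> None:
    rows = []
    for r in records:
        row = {
            "feature_id": r.feature_id, "mz": r.mz, "rt_apex": r.rt_apex,
            "rt_min": r.rt_min, "rt_max": r.rt_max,
        }
        row.update({f"height_{k}": v for k, v in r.per_sample_height.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _read_table(path: str) -> pd.DataFrame:
    sep = "\t" if path.lower().endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# EIC extraction
# ---------------------------------------------------------------------------

def mz_tolerance(mz: float) -> float:
    """Extraction half-window: 0.01 Da below 400 Da, else 25 ppm."""
    return MZ_TOL_DA_LOW_MASS if mz < MZ_TOL_SWITCH_DA else mz * MZ_TOL_PPM * 1e-6


def extract_eic(
    run: RawRun,
    mz: float,
    rt_window: tuple[float, float],
    mz_tol: float | None = None,
) -> EIC:
    """Extract an ion chromatogram for one m/z window.

    For every MS1 scan inside ``rt_window`` (closed interval), the EIC
    intensity is the sum of centroid intensities with |mz_i − mz| ≤ tol.
    Scans with no matching centroid contribute an explicit zero so EIC
    grids from one run are shared across isotopologues.
    """
    tol = mz_tolerance(mz) if mz_tol is None else mz_tol
    lo, hi = rt_window
    rts: list[float] = []
    intens: list[float] = []
    for scan in run.scans:
        if scan.rt < lo or scan.rt > hi:
            continue
        i0 = np.searchsorted(scan.mz, mz - tol, side="left")
        i1 = np.searchsorted(scan.mz, mz + tol, side="right")
        rts.append(scan.rt)
        intens.append(float(scan.intensity[i0:i1].sum()))
    return EIC(mz_center=mz, mz_tol=tol, rt=np.array(rts), intensity=np.array(intens),
               run_id=run.run_id)


def extract_eics_multi(
    run: RawRun,
    mz_list: Sequence[float],
    rt_window: tuple[float, float],
) -> list[EIC]:
    """Extract several m/z channels over one shared RT window in one pass.

    Equivalent to calling :func:`extract_eic` per channel but iterates the
    scan list once, which matters when a run is interrogated for thousands
    of isotopologue channels.
    """
    mzs = np.asarray(mz_list, dtype=float)
    tols = np.array([mz_tolerance(m) for m in mzs])
    lo, hi = rt_window
    scans = [s for s in run.scans if lo <= s.rt <= hi]
    rts = np.array([s.rt for s in scans])
    out = np.zeros((len(mzs), len(scans)))
    for j, scan in enumerate(scans):
        i0 = np.searchsorted(scan.mz, mzs - tols, side="left")
        i1 = np.searchsorted(scan.mz, mzs + tols, side="right")
        csum = np.concatenate([[0.0], np.cumsum(scan.intensity)])
        out[:, j] = csum[i1] - csum[i0]
    return [
        EIC(mz_center=float(mzs[i]), mz_tol=float(tols[i]), rt=rts.copy(),
            intensity=out[i], run_id=run.run_id)
        for i in range(len(mzs))
    ]


# ---------------------------------------------------------------------------
# MID table
# ---------------------------------------------------------------------------

MID_TABLE_COLUMNS = (
    "metabolite_id", "isotopologue_index", "run_id", "group",
    "corrected_intensity", "labeled_fraction",
)


def write_mid_table(mids: pd.DataFrame, path: str) -> None:
    """Write the long-format MID table (the pipeline's final output).

    Columns: metabolite_id, isotopologue_index, run_id, group,
    corrected_intensity, labeled_fraction.  Fractions outside [0, 1]
    are a validation error.
    """
    missing = set(MID_TABLE_COLUMNS) - set(mids.columns)
    if missing:
        raise SchemaError(f"MID table missing columns: {sorted(missing)}")
    frac = mids["labeled_fraction"].to_numpy(dtype=float)
    bad = (frac < -1e-12) | (frac > 1 + 1e-12)
    if np.any(bad):
        raise ValidationError(
            f"labeled_fraction outside [0,1] in {int(bad.sum())} rows "
            f"(first offending value {frac[bad][0]!r})"
        )
    mids.loc[:, list(MID_TABLE_COLUMNS)].to_csv(path, index=False, float_format="%.15g")


def read_mid_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MID_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"MID table {path!r} missing columns: {sorted(missing)}")
    df["metabolite_id"] = df["metabolite_id"].astype(str)
    df["run_id"] = df["run_id"].astype(str)
    df["group"] = df["group"].astype(str)
    return df
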