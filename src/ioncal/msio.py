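"""mzML input/output and fragment-intensity extraction.

Reads centroided MS2 spectra from mzML, extracts fragment-panel
intensities for infusion calibration, and builds per-analyte DIA
chromatograms from a transition list.

The mzML layer is a compact lxml-based parser/writer covering the
subset of the standard this package needs: centroided MSn spectra with
scan start time, ion injection time, precursor isolation windows, and
32/64-bit float peak arrays (zlib-compressed or plain base64). Indexed
and plain mzML are both accepted (the index wrapper is ignored).

Ion injection time is carried in milliseconds, as stored in mzML; all
ion arithmetic downstream converts to seconds at the point where
``ions = intensity * time`` is formed.
"""

from __future__ import annotations

import base64
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "SpectrumRecord",
    "FragmentPanel",
    "FragmentIntensityMatrix",
    "TransitionTarget",
    "Chromatogram",
    "MzmlError",
    "read_ms2_spectra",
    "write_mzml",
    "read_panel_csv",
    "read_transition_csv",
    "extract_fragment_intensities",
    "extract_dia_chromatograms",
]


class MzmlError(ValueError):
    """Raised for malformed mzML or missing required scan metadata."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpectrumRecord:
    """One centroided MS2 scan.

    Attributes
    ----------
    scan_index : int
        0-based position of the scan in the run.
    retention_time : float
        Scan start time in minutes.
    ms_level : int
    isolation_center, isolation_width : float
        Precursor isolation window center and full width (m/z). NaN when
        the scan carries no isolation window (e.g. MS1).
    injection_time : float
        Ion injection (accumulation) time in milliseconds. Must be > 0;
        ion-count arithmetic is undefined without it.
    mz_values : np.ndarray
        Strictly ascending centroid m/z values.
    intensities : np.ndarray
        Non-negative intensities, same length as ``mz_values``.
    tic : float
        Total ion current. Recomputed as ``intensities.sum()`` unless a
        vendor value is supplied.
    """

    scan_index: int
    retention_time: float
    ms_level: int
    isolation_center: float
    isolation_width: float
    injection_time: float
    mz_values: np.ndarray
    intensities: np.ndarray
    tic: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.mz_values.shape != self.intensities.shape:
            raise ValueError(
                f"scan {self.scan_index}: m/z and intensity arrays differ in "
                f"length ({self.mz_values.size} vs {self.intensities.size})"
            )
        if self.mz_values.size > 1 and not np.all(np.diff(self.mz_values) > 0):
            raise ValueError(f"scan {self.scan_index}: m/z values not strictly ascending")
        if np.any(self.intensities < 0):
            raise ValueError(f"scan {self.scan_index}: negative intensity")
        if not self.injection_time > 0:
            raise ValueError(
                f"scan {self.scan_index}: injection time must be positive "
                f"(got {self.injection_time!r})"
            )
        if np.isnan(self.tic):
            self.tic = float(self.intensities.sum())
        if self.tic < 0:
            raise ValueError(f"scan {self.scan_index}: negative TIC")

    @property
    def injection_time_sec(self) -> float:
        return self.injection_time * 1e-3

    def window_contains(self, mz: float) -> bool:
        """Half-open membership test [center - w/2, center + w/2).

        Half-open on the upper edge so adjacent non-staggered DIA windows
        partition the precursor axis without double counting.
        """
        if np.isnan(self.isolation_center) or np.isnan(self.isolation_width):
            return False
        lo = self.isolation_center - self.isolation_width / 2.0
        hi = self.isolation_center + self.isolation_width / 2.0
        return lo <= mz < hi


@dataclass(frozen=True)
class FragmentPanel:
    """Fragment ions used for ratio calibration, one designated reference.

    ``tolerance`` is interpreted in ``tolerance_unit``: "ppm" (relative)
    or "mz" (absolute Th). Targets must be mutually separated by more
    than twice the absolute tolerance so centroid matching is unambiguous.
    """

    target_mzs: tuple
    reference_mz: float
    tolerance: float
    tolerance_unit: str = "ppm"

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_mzs", tuple(float(m) for m in self.target_mzs))
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.tolerance_unit not in ("ppm", "mz"):
            raise ValueError(f"tolerance_unit must be 'ppm' or 'mz', got {self.tolerance_unit!r}")
        if not any(np.isclose(self.reference_mz, m) for m in self.target_mzs):
            raise ValueError("reference_mz must be one of target_mzs")
        mzs = np.sort(np.asarray(self.target_mzs))
        if mzs.size > 1:
            gaps = np.diff(mzs)
            limits = 2.0 * self.abs_tolerance(mzs[1:])
            if np.any(gaps <= limits):
                raise ValueError(
                    "panel m/z targets closer than 2x the matching tolerance; "
                    "matching would be ambiguous"
                )

    def abs_tolerance(self, mz) -> np.ndarray:
        """Absolute tolerance in Th at the given m/z."""
        mz = np.asarray(mz, dtype=float)
        if self.tolerance_unit == "ppm":
            return mz * self.tolerance * 1e-6
        return np.broadcast_to(np.float64(self.tolerance), mz.shape).copy()


@dataclass
class FragmentIntensityMatrix:
    """Extracted intensities, spectra x panel fragments.

    A value of 0 means no centroid matched within tolerance.
    """

    spectrum_indices: np.ndarray
    fragment_mzs: np.ndarray
    values: np.ndarray
    injection_times: np.ndarray  # milliseconds, per spectrum

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spectrum_indices = np.asarray(self.spectrum_indices)
        self.fragment_mzs = np.asarray(self.fragment_mzs, dtype=np.float64)
        self.injection_times = np.asarray(self.injection_times, dtype=np.float64)
        n_spec, n_frag = self.values.shape
        if self.spectrum_indices.size != n_spec or self.injection_times.size != n_spec:
            raise ValueError("per-spectrum arrays inconsistent with value matrix")
        if self.fragment_mzs.size != n_frag:
            raise ValueError("fragment list inconsistent with value matrix")
        if np.any(self.values < 0):
            raise ValueError("negative extracted intensity")

    def column(self, mz: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.fragment_mzs - mz)))
        if not np.isclose(self.fragment_mzs[j], mz):
            raise KeyError(f"fragment m/z {mz} not in matrix")
        return self.values[:, j]


@dataclass(frozen=True)
class TransitionTarget:
    """One analyte's transitions and its LC peak integration boundary."""

    analyte_id: str
    precursor_mz: float
    fragment_mzs: tuple
    tolerance: float = 10.0
    tolerance_unit: str = "ppm"
    boundary_start: float = 0.0  # minutes
    boundary_end: float = np.inf

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment_mzs", tuple(float(m) for m in self.fragment_mzs))
        if not self.fragment_mzs:
            raise ValueError(f"{self.analyte_id}: empty fragment list")
        if not self.boundary_start < self.boundary_end:
            raise ValueError(f"{self.analyte_id}: boundary_start must precede boundary_end")
        if self.tolerance <= 0:
            raise ValueError(f"{self.analyte_id}: tolerance must be positive")

    def abs_tolerance(self, mz) -> np.ndarray:
        mz = np.asarray(mz, dtype=float)
        if self.tolerance_unit == "ppm":
            return mz * self.tolerance * 1e-6
        return np.broadcast_to(np.float64(self.tolerance), mz.shape).copy()


@dataclass
class Chromatogram:
    """Per-analyte DIA trace: one point per contributing MS2 scan."""

    analyte_id: str
    retention_times: np.ndarray  # minutes
    intensities: np.ndarray  # summed transition intensity
    tics: np.ndarray
    injection_times: np.ndarray  # milliseconds

    def __len__(self) -> int:
        return self.retention_times.size


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------

def _matched_intensity(spectrum: SpectrumRecord, target_mz: float, tol: float) -> float:
    """Most intense centroid within +-tol of target_mz, 0 if none.

    Most-intense (not nearest-m/z) wins: robust to small mass-calibration
    jitter around a prominent fragment.
    """
    mz = spectrum.mz_values
    lo = np.searchsorted(mz, target_mz - tol, side="left")
    hi = np.searchsorted(mz, target_mz + tol, side="right")
    if hi <= lo:
        return 0.0
    return float(spectrum.intensities[lo:hi].max())


def read_ms2_spectra(
    path: str | Path,
    ms_level_filter: int = 2,
    rt_range: tuple[float, float] | None = None,
    use_vendor_tic: bool = False,
) -> list[SpectrumRecord]:
    """Read centroided spectra of one MS level from an mzML file.

    Parameters
    ----------
    path : str or Path
    ms_level_filter : int
        Keep only spectra at this MS level (default 2).
    rt_range : (float, float), optional
        Half-open retention-time filter in minutes: keep ``lo <= rt < hi``.
    use_vendor_tic : bool
        Take the vendor-reported total ion current cvParam instead of
        recomputing the sum of centroid intensities (the default).

    Returns
    -------
    list of SpectrumRecord, sorted by retention time.

    Raises
    ------
    MzmlError
        On malformed mzML, profile-mode spectra, or spectra missing ion
        injection time metadata (the ions/sec calibration is undefined
        without the accumulation time).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SpectrumRecord] = []
    spectrum_tag = f"{{{_NS}}}spectrum"
    try:
        context = etree.iterparse(str(path), events=("end",), tag=spectrum_tag)
        for i, (_, elem) in enumerate(context):
            rec = _parse_spectrum(elem, i, use_vendor_tic)
            if rec is not None and rec.ms_level == ms_level_filter:
                records.append(rec)
            # free parsed subtree (iterparse keeps ancestors otherwise)
            elem.clear()
            parent = elem.getparent()
            while parent is not None and elem.getprevious() is not None:
                del parent[0]
    except etree.XMLSyntaxError as exc:
        raise MzmlError(f"malformed mzML in {path.name}: {exc}") from exc
    if rt_range is not None:
        lo, hi = rt_range
        records = [r for r in records if lo <= r.retention_time < hi]
    records.sort(key=lambda r: r.retention_time)
    return records


def _cv_params(elem) -> dict[str, str]:
    """accession -> value for all cvParam descendants of elem."""
    return {cv.get("accession"): cv for cv in elem.iter(f"{{{_NS}}}cvParam")}


def _own_cv_params(elem) -> dict[str, str]:
    return {cv.get("accession"): cv for cv in elem.findall(f"{{{_NS}}}cvParam")}


def _parse_spectrum(elem, index: int, use_vendor_tic: bool) -> SpectrumRecord | None:
    sid = elem.get("id", f"index {index}")
    own = _own_cv_params(elem)
    if "MS:1000511" not in own:
        raise MzmlError(f"scan {sid}: missing ms level cvParam")
    level = int(own["MS:1000511"].get("value"))
    if "MS:1000128" in own:
        raise MzmlError(
            f"scan {sid} is profile mode; centroid the data upstream "
            "(e.g. msconvert --filter 'peakPicking') before reading"
        )
    scan = elem.find(f"{{{_NS}}}scanList/{{{_NS}}}scan")
    if scan is None:
        raise MzmlError(f"scan {sid}: no scan metadata")
    scan_cv = _own_cv_params(scan)
    if "MS:1000016" not in scan_cv:
        raise MzmlError(f"scan {sid}: missing scan start time")
    rt_cv = scan_cv["MS:1000016"]
    rt_min = float(rt_cv.get("value"))
    if rt_cv.get("unitName") == "second" or rt_cv.get("unitAccession") == "UO:0000010":
        rt_min /= 60.0
    if "MS:1000927" not in scan_cv:
        raise MzmlError(
            f"scan {sid}: missing ion injection time metadata; "
            "ion-count calibration is undefined without it"
        )
    injection_time = float(scan_cv["MS:1000927"].get("value"))
    iso_center = np.nan
    iso_width = np.nan
    win = elem.find(
        f"{{{_NS}}}precursorList/{{{_NS}}}precursor/{{{_NS}}}isolationWindow"
    )
    if win is not None:
        win_cv = _own_cv_params(win)
        if "MS:1000827" in win_cv:
            iso_center = float(win_cv["MS:1000827"].get("value"))
            lo_off = float(win_cv.get("MS:1000828").get("value")) if "MS:1000828" in win_cv else 0.0
            hi_off = float(win_cv.get("MS:1000829").get("value")) if "MS:1000829" in win_cv else 0.0
            iso_width = lo_off + hi_off
    arrays: dict[str, np.ndarray] = {}
    for ba in elem.findall(f"{{{_NS}}}binaryDataArrayList/{{{_NS}}}binaryDataArray"):
        ba_cv = _own_cv_params(ba)
        if "MS:1000514" in ba_cv:
            kind = "mz"
        elif "MS:1000515" in ba_cv:
            kind = "intensity"
        else:
            continue
        dtype = "<f8" if "MS:1000523" in ba_cv else "<f4"
        binary = ba.find(f"{{{_NS}}}binary")
        raw = base64.b64decode(binary.text or "")
        if "MS:1000574" in ba_cv:  # zlib
            raw = zlib.decompress(raw)
        arrays[kind] = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    if "mz" not in arrays or "intensity" not in arrays:
        raise MzmlError(f"scan {sid}: missing m/z or intensity array")
    tic = np.nan
    if use_vendor_tic and "MS:1000285" in own:
        tic = float(own["MS:1000285"].get("value"))
    try:
        return SpectrumRecord(
            scan_index=index,
            retention_time=rt_min,
            ms_level=level,
            isolation_center=iso_center,
            isolation_width=iso_width,
            injection_time=injection_time,
            mz_values=arrays["mz"],
            intensities=arrays["intensity"],
            tic=tic,
        )
    except ValueError as exc:
        raise MzmlError(f"scan {sid}: {exc}") from exc


# ---------------------------------------------------------------------------
# mzML writing
# ---------------------------------------------------------------------------

_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession: str, name: str, value: str = "") -> None:
    el = etree.SubElement(parent, "cvParam")
    el.set("cvRef", "MS")
    el.set("accession", accession)
    el.set("name", name)
    el.set("value", value)


def _encode_array(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(raw).decode("ascii")


def write_mzml(spectra: Sequence[SpectrumRecord], path: str | Path) -> None:
    """Write centroided spectra to a minimal mzML 1.1.0 file.

    Arrays are encoded as uncompressed little-endian 64-bit floats, so a
    read-back through :func:`read_ms2_spectra` reproduces m/z, intensity,
    injection time and retention time exactly. Output contains no
    timestamps: identical inputs give byte-identical files.
    """
    path = Path(path)
    root = etree.Element("mzML", nsmap={None: _NS})
    root.set("version", "1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(
        cv_list,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    run = etree.SubElement(root, "run", id="run")
    slist = etree.SubElement(run, "spectrumList", count=str(len(spectra)))
    for i, rec in enumerate(spectra):
        sp = etree.SubElement(
            slist,
            "spectrum",
            index=str(i),
            id=f"scan={rec.scan_index}",
            defaultArrayLength=str(rec.mz_values.size),
        )
        _cv(sp, "MS:1000511", "ms level", str(rec.ms_level))
        _cv(sp, "MS:1000580", "MSn spectrum")
        _cv(sp, "MS:1000127", "centroid spectrum")
        _cv(sp, "MS:1000285", "total ion current", repr(float(rec.tic)))
        scan_list = etree.SubElement(sp, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        el = etree.SubElement(scan, "cvParam")
        el.set("cvRef", "MS")
        el.set("accession", "MS:1000016")
        el.set("name", "scan start time")
        el.set("value", repr(float(rec.retention_time)))
        el.set("unitCvRef", "UO")
        el.set("unitAccession", "UO:0000031")
        el.set("unitName", "minute")
        el = etree.SubElement(scan, "cvParam")
        el.set("cvRef", "MS")
        el.set("accession", "MS:1000927")
        el.set("name", "ion injection time")
        el.set("value", repr(float(rec.injection_time)))
        el.set("unitCvRef", "UO")
        el.set("unitAccession", "UO:0000028")
        el.set("unitName", "millisecond")
        if np.isfinite(rec.isolation_center):
            plist = etree.SubElement(sp, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            win = etree.SubElement(prec, "isolationWindow")
            _cv(win, "MS:1000827", "isolation window target m/z", repr(float(rec.isolation_center)))
            half = float(rec.isolation_width) / 2.0
            _cv(win, "MS:1000828", "isolation window lower offset", repr(half))
            _cv(win, "MS:1000829", "isolation window upper offset", repr(half))
        balist = etree.SubElement(sp, "binaryDataArrayList", count="2")
        for accession, name, arr in (
            ("MS:1000514", "m/z array", rec.mz_values),
            ("MS:1000515", "intensity array", rec.intensities),
        ):
            encoded = _encode_array(arr)
            ba = etree.SubElement(balist, "binaryDataArray", encodedLength=str(len(encoded)))
            _cv(ba, "MS:1000523", "64-bit float")
            _cv(ba, "MS:1000576", "no compression")
            _cv(ba, accession, name)
            b = etree.SubElement(ba, "binary")
            b.text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# Panel / transition CSV readers
# ---------------------------------------------------------------------------

def read_panel_csv(path: str | Path) -> FragmentPanel:
    """Read a fragment panel: columns target_mz, is_reference, tolerance,
    tolerance_unit; exactly one row flagged as reference."""
    df = pd.read_csv(path)
    required = {"target_mz", "is_reference", "tolerance", "tolerance_unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing column(s): {', '.join(sorted(missing))}")
    ref_mask = df["is_reference"].astype(bool)
    if ref_mask.sum() != 1:
        raise ValueError("panel file must flag exactly one reference fragment")
    return FragmentPanel(
        target_mzs=tuple(df["target_mz"].astype(float)),
        reference_mz=float(df.loc[ref_mask, "target_mz"].iloc[0]),
        tolerance=float(df["tolerance"].iloc[0]),
        tolerance_unit=str(df["tolerance_unit"].iloc[0]),
    )


def read_transition_csv(path: str | Path, tolerance: float = 10.0,
                        tolerance_unit: str = "ppm") -> list[TransitionTarget]:
    """Read a transition list, one row per transition.

    Columns: analyte_id, precursor_mz, fragment_mz, boundary_start_min,
    boundary_end_min.
    """
    df = pd.read_csv(path)
    required = {"analyte_id", "precursor_mz", "fragment_mz",
                "boundary_start_min", "boundary_end_min"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transition file missing column(s): {', '.join(sorted(missing))}")
    if df.empty:
        raise ValueError("transition file contains no transitions")
    targets = []
    for aid, grp in df.groupby("analyte_id", sort=True):
        targets.append(
            TransitionTarget(
                analyte_id=str(aid),
                precursor_mz=float(grp["precursor_mz"].iloc[0]),
                fragment_mzs=tuple(grp["fragment_mz"].astype(float)),
                tolerance=tolerance,
                tolerance_unit=tolerance_unit,
                boundary_start=float(grp["boundary_start_min"].iloc[0]),
                boundary_end=float(grp["boundary_end_min"].iloc[0]),
            )
        )
    return targets


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_fragment_intensities(
    spectra: Sequence[SpectrumRecord], panel: FragmentPanel
) -> FragmentIntensityMatrix:
    """Extract the panel fragments from every spectrum.

    Each cell holds the intensity of the most intense centroid within
    ±tolerance of the target m/z, or 0 when no centroid matched.
    Row order follows the input spectrum order.
    """
    if not spectra:
        raise ValueError("no spectra to extract from")
    mzs = np.asarray(panel.target_mzs)
    tols = panel.abs_tolerance(mzs)
    values = np.zeros((len(spectra), mzs.size))
    for i, rec in enumerate(spectra):
        for j, (mz, tol) in enumerate(zip(mzs, tols)):
            values[i, j] = _matched_intensity(rec, mz, tol)
    return FragmentIntensityMatrix(
        spectrum_indices=np.asarray([r.scan_index for r in spectra]),
        fragment_mzs=mzs,
        values=values,
        injection_times=np.asarray([r.injection_time for r in spectra]),
    )


def extract_dia_chromatograms(
    spectra: Sequence[SpectrumRecord], targets: Sequence[TransitionTarget]
) -> dict[str, Chromatogram]:
    """Build one chromatogram per transition target from a DIA run.

    A spectrum contributes to a target iff its isolation window contains
    the precursor m/z (half-open on the upper edge). The point's
    intensity is the sum over the target's fragment m/z values of the
    matched-centroid intensities (0 for unmatched fragments).

    Targets matching no spectra yield an empty chromatogram with a
    warning rather than an error.
    """
    out: dict[str, Chromatogram] = {}
    for target in targets:
        rts, sums, tics, its = [], [], [], []
        tols = target.abs_tolerance(np.asarray(target.fragment_mzs))
        for rec in spectra:
            if rec.ms_level != 2 or not rec.window_contains(target.precursor_mz):
                continue
            total = 0.0
            for mz, tol in zip(target.fragment_mzs, tols):
                total += _matched_intensity(rec, mz, tol)
            rts.append(rec.retention_time)
            sums.append(total)
            tics.append(rec.tic)
            its.append(rec.injection_time)
        if not rts:
            warnings.warn(
                f"target {target.analyte_id}: precursor {target.precursor_mz} "
                "matched no isolation window; empty chromatogram",
                stacklevel=2,
            )
        out[target.analyte_id] = Chromatogram(
            analyte_id=target.analyte_id,
            retention_times=np.asarray(rts),
            intensities=np.asarray(sums),
            tics=np.asarray(tics),
            injection_times=np.asarray(its),
        )
    return out
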