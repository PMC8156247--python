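"""Precursor screening and MS/MS fragment annotation against cyclic candidates.

Matching is deterministic: each theoretical library entry is assigned the
nearest observed peak inside a ppm window (with an absolute floor for the
low-mass immonium region), and at most one peak per library entry.
Score = n_matched + coverage; no probabilistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import ppm_delta
from .fragments import FragmentIon, FragmentLibrary
from .ptm import CyclicPeptideCandidate

__all__ = [
    "Spectrum",
    "SpectrumMatch",
    "MatchReport",
    "read_mgf",
    "write_mgf",
    "read_peaklist",
    "screen_precursors",
    "annotate_fragments",
    "build_report",
    "DEFAULT_PRECURSOR_TOL_PPM",
    "DEFAULT_FRAGMENT_TOL_PPM",
    "FRAGMENT_TOL_FLOOR_DA",
]

DEFAULT_PRECURSOR_TOL_PPM = 5.0
DEFAULT_FRAGMENT_TOL_PPM = 10.0
# ppm windows shrink below instrument resolution at immonium masses.
FRAGMENT_TOL_FLOOR_DA = 0.002


@dataclass
class Spectrum:
    """A peak list with precursor information; peaks kept sorted by m/z."""

    id: str
    precursor_mz: float
    precursor_charge: int = 1
    peaks: list[tuple[float, float]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.id!r}: precursor m/z must be > 0")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"spectrum {self.id!r}: negative intensity")
        self.peaks = sorted(self.peaks)


@dataclass
class SpectrumMatch:
    spectrum_id: str
    candidate: CyclicPeptideCandidate
    theoretical_mz: float
    precursor_ppm: float | None
    matched_ions: list[tuple[FragmentIon, tuple[float, float], float]]  # ion, peak, ppm
    n_matched: int
    coverage: float

    @property
    def score(self) -> float:
        return self.n_matched + self.coverage


def read_mgf(path) -> list[Spectrum]:
    """Read a Mascot generic format file (BEGIN IONS / END IONS blocks)."""
    spectra: list[Spectrum] = []
    in_block = False
    params: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise ValueError(f"line {lineno}: nested BEGIN IONS")
                in_block, params, peaks = True, {}, []
            elif line == "END IONS":
                if not in_block:
                    raise ValueError(f"line {lineno}: END IONS without BEGIN IONS")
                if "PEPMASS" not in params:
                    raise ValueError(f"line {lineno}: spectrum block lacks PEPMASS")
                charge = 1
                if "CHARGE" in params:
                    charge = int(params["CHARGE"].rstrip("+").lstrip("-") or 1)
                spectra.append(
                    Spectrum(
                        id=params.get("TITLE", f"spectrum_{len(spectra) + 1}"),
                        precursor_mz=float(params["PEPMASS"].split()[0]),
                        precursor_charge=charge,
                        peaks=peaks,
                        metadata=dict(params),
                    )
                )
                in_block = False
            elif in_block:
                if "=" in line and not line[0].isdigit():
                    key, _, value = line.partition("=")
                    params[key.upper()] = value
                else:
                    fields = line.split()
                    try:
                        mz = float(fields[0])
                        intensity = float(fields[1]) if len(fields) > 1 else 0.0
                    except (IndexError, ValueError):
                        raise ValueError(f"line {lineno}: malformed peak line {line!r}") from None
                    peaks.append((mz, intensity))
    if in_block:
        raise ValueError("unterminated BEGIN IONS block at end of file")
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for mz, intensity in s.peaks:
                fh.write(f"{mz:.6f} {intensity:.6f}\n")
            fh.write("END IONS\n\n")


def read_peaklist(path) -> Spectrum:
    """Read the two-column text format: header 'PRECURSOR <mz> <charge>' then
    'mz intensity' lines."""
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0].upper() != "PRECURSOR":
            raise ValueError("peak list must start with 'PRECURSOR <mz> <charge>'")
        precursor_mz = float(header[1])
        charge = int(header[2]) if len(header) > 2 else 1
        peaks = []
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.split()
            try:
                peaks.append((float(fields[0]), float(fields[1]) if len(fields) > 1 else 0.0))
            except (IndexError, ValueError):
                raise ValueError(f"line {lineno}: malformed peak line {line!r}") from None
    import os

    return Spectrum(id=os.path.basename(str(path)), precursor_mz=precursor_mz,
                    precursor_charge=charge, peaks=peaks)


def screen_precursors(
    spectra: list[Spectrum],
    candidates: list[CyclicPeptideCandidate],
    tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
) -> list[tuple[Spectrum, CyclicPeptideCandidate, float]]:
    """All (spectrum, candidate) pairs whose precursor m/z agrees within tol_ppm.

    The signed ppm is computed against the candidate's 4-decimal reported
    theoretical m/z, matching the precision convention of the report tables.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    out = []
    for s in spectra:
        for c in candidates:
            ppm = ppm_delta(s.precursor_mz, round(c.mz, 4))
            if abs(ppm) <= tol_ppm:
                out.append((s, c, ppm))
    return out


def annotate_fragments(
    spectrum: Spectrum,
    library: FragmentLibrary,
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    min_intensity_fraction: float = 0.0,
    candidate: CyclicPeptideCandidate | None = None,
) -> SpectrumMatch:
    """Annotate a spectrum's peaks with a candidate's fragment library.

    Each library entry takes the nearest peak within max(tol_ppm window,
    absolute floor); a peak may annotate several isobaric entries but each
    entry matches at most one peak.  Coverage is the fraction of arc lengths
    1..n-1 with at least one matched arc ion.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if not 0 <= min_intensity_fraction < 1:
        raise ValueError("min_intensity_fraction must be in [0, 1)")
    peaks = spectrum.peaks
    if peaks and min_intensity_fraction > 0:
        cutoff = min_intensity_fraction * max(i for _, i in peaks)
        peaks = [p for p in peaks if p[1] >= cutoff]

    matched: list[tuple[FragmentIon, tuple[float, float], float]] = []
    matched_labels: set[str] = set()
    for ion in library.ions:
        window = max(ion.mz * tol_ppm * 1e-6, FRAGMENT_TOL_FLOOR_DA)
        best = None
        for peak in peaks:  # peak lists are short; linear scan is fine
            err = abs(peak[0] - ion.mz)
            if err <= window and (best is None or err < abs(best[0] - ion.mz)):
                best = peak
        if best is not None and ion.label not in matched_labels:
            matched.append((ion, best, ppm_delta(best[0], ion.mz)))
            matched_labels.add(ion.label)

    n = len(library.core)
    lengths_present = {
        len(ion.subsequence)
        for ion in library.ions
        if ion.kind not in ("precursor", "precursor-NH3", "precursor-H2O")
        and len(ion.subsequence) < n
    }
    lengths_hit = {
        len(ion.subsequence)
        for ion, _, _ in matched
        if ion.kind not in ("precursor", "precursor-NH3", "precursor-H2O")
        and len(ion.subsequence) < n
    }
    coverage = len(lengths_hit) / len(lengths_present) if lengths_present else 0.0

    theoretical = candidate.mz if candidate is not None else library.precursor_mz
    precursor_ppm = ppm_delta(spectrum.precursor_mz, theoretical)
    return SpectrumMatch(
        spectrum_id=spectrum.id,
        candidate=candidate,
        theoretical_mz=theoretical,
        precursor_ppm=precursor_ppm,
        matched_ions=matched,
        n_matched=len(matched),
        coverage=coverage,
    )


@dataclass
class MatchReport:
    """Per-candidate rows: (name, formula, theoretical, measured|N/A, ppm|N/A,
    n_matched|N/A, isobaric flag)."""

    rows: list[dict] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        cols = ["candidate", "formula", "theoretical_mz", "measured_mz",
                "delta_ppm", "n_matched_fragments", "isobaric"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def build_report(
    screen_results: list[tuple[Spectrum, CyclicPeptideCandidate, float]],
    annotations: dict[str, SpectrumMatch],
    candidates: list[CyclicPeptideCandidate],
) -> MatchReport:
    """One row per candidate; unmatched candidates carry N/A measured/ppm.

    ``annotations`` maps candidate name -> best SpectrumMatch (optional).
    Candidates sharing a 4-decimal theoretical m/z are flagged isobaric.
    """
    best: dict[str, tuple[Spectrum, float]] = {}
    for spectrum, candidate, ppm in screen_results:
        cur = best.get(candidate.name)
        if cur is None or abs(ppm) < abs(cur[1]):
            best[candidate.name] = (spectrum, ppm)

    mz_counts: dict[float, int] = {}
    for c in candidates:
        key = round(c.mz, 4)
        mz_counts[key] = mz_counts.get(key, 0) + 1

    report = MatchReport()
    for c in candidates:
        hit = best.get(c.name)
        ann = annotations.get(c.name)
        report.rows.append({
            "candidate": c.name,
            "formula": c.formula.hill(),
            "theoretical_mz": f"{c.mz:.4f}",
            "measured_mz": f"{hit[0].precursor_mz:.4f}" if hit else "N/A",
            "delta_ppm": f"{hit[1]:.4f}" if hit else "N/A",
            "n_matched_fragments": ann.n_matched if ann else "N/A",
            "isobaric": mz_counts[round(c.mz, 4)] > 1,
        })
    return report
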