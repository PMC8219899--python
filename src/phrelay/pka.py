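"""Ensemble pKa aggregation from PROPKA 3.1 output.

PROPKA is treated strictly as an upstream tool: one ``.pka`` file per
trajectory frame is parsed, never recomputed.  Of particular interest is
PROPKA's carboxyl-carboxyl coupling detection: when two acidic side
chains sit close enough that protonating one is stabilized by the
other (a protonated dyad), the program reports two alternative pKa
values — in alternative *a* the first group is protonated and
stabilized by the second, in alternative *b* the roles are reversed.
Aggregation reports, per residue, the mean +/- SD over all frames and
over coupling frames only, the percentage of coupling frames, and the
fraction of the distribution inside a critical pH window (default
[6, 7], the physiologically relevant range between the extracellular
medium and the early endosome).

The parser reads the ``SUMMARY OF THIS PREDICTION`` block of a PROPKA
3.1 file plus an optional ``COUPLED RESIDUES`` block listing the two
alternative states; labels *a*/*b* are preserved from file order, never
inferred.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CRITICAL_WINDOW = (6.0, 7.0)


@dataclass
class PkaRecord:
    """pKa of one titratable residue in one frame."""

    frame: int
    residue: str                   # e.g. "D308"
    pka: float
    coupled: bool = False
    partner: str | None = None
    alternative_a: float | None = None
    alternative_b: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.pka):
            raise ValueError(f"non-finite pKa for {self.residue}")
        if self.coupled and (self.partner is None
                             or self.alternative_a is None
                             or self.alternative_b is None):
            raise ValueError(f"coupled record for {self.residue} lacks "
                             "partner or alternative values")


_ONE_TO_THREE = {"D": "ASP", "E": "GLU", "H": "HIS", "K": "LYS", "R": "ARG",
                 "C": "CYS", "Y": "TYR"}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}

_SUMMARY_RE = re.compile(
    r"^\s*([A-Z]{3})\s+(\d+)\s+([A-Z])\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)")
_COUPLE_RE = re.compile(
    r"^\s*([A-Z]{3})\s+(\d+)\s+([A-Z])\s+coupled to\s+([A-Z]{3})\s+(\d+)\s+([A-Z])")
_ALT_RE = re.compile(
    r"^\s*alternative\s+([ab]):\s+([A-Z]{3})\s+(\d+)\s+[A-Z]\s+(-?\d+\.\d+)"
    r"\s+([A-Z]{3})\s+(\d+)\s+[A-Z]\s+(-?\d+\.\d+)")


def _short(res3: str, num: int) -> str:
    return f"{_THREE_TO_ONE.get(res3, 'X')}{num}"


def parse_propka(paths: list[str | Path], frames: list[int] | None = None
                 ) -> list[PkaRecord]:
    """Parse PROPKA 3.1 summary files, one per frame.

    ``frames`` assigns frame ids (defaults to file order).  Malformed
    files raise with the offending line number; residues absent from a
    frame simply yield no record for that frame.
    """
    records: list[PkaRecord] = []
    frames = frames if frames is not None else list(range(len(paths)))
    for frame, path in zip(frames, paths):
        records.extend(_parse_one(Path(path), frame))
    return records


def _parse_one(path: Path, frame: int) -> list[PkaRecord]:
    lines = path.read_text().splitlines()
    in_summary = in_coupling = False
    base: dict[str, float] = {}
    couples: dict[str, dict] = {}
    saw_summary = False
    for ln, line in enumerate(lines, start=1):
        stripped = line.strip()
        if "SUMMARY OF THIS PREDICTION" in line:
            in_summary, in_coupling, saw_summary = True, False, True
            continue
        if "COUPLED RESIDUES" in line:
            in_summary, in_coupling = False, True
            continue
        if in_summary:
            if not stripped or stripped.startswith(("Group", "-")):
                if stripped.startswith("-"):
                    in_summary = False
                continue
            m = _SUMMARY_RE.match(line)
            if not m:
                raise ValueError(f"{path}:{ln}: unparseable summary line: "
                                 f"{line!r}")
            res3, num = m.group(1), int(m.group(2))
            base[_short(res3, num)] = float(m.group(4))
        elif in_coupling and stripped:
            m = _COUPLE_RE.match(line)
            if m:
                a = _short(m.group(1), int(m.group(2)))
                b = _short(m.group(4), int(m.group(5)))
                couples[a] = {"partner": b}
                couples[b] = {"partner": a}
                continue
            m = _ALT_RE.match(line)
            if m:
                alt = m.group(1)
                r1 = _short(m.group(2), int(m.group(3)))
                r2 = _short(m.group(5), int(m.group(6)))
                for res, val in ((r1, float(m.group(4))), (r2, float(m.group(7)))):
                    couples.setdefault(res, {})[f"alternative_{alt}"] = val
                continue
            raise ValueError(f"{path}:{ln}: unparseable coupling line: {line!r}")
    if not saw_summary:
        raise ValueError(f"{path}:1: no 'SUMMARY OF THIS PREDICTION' block")
    out = []
    for res, pka in base.items():
        info = couples.get(res)
        if info is None:
            out.append(PkaRecord(frame, res, pka))
        else:
            out.append(PkaRecord(frame, res, pka, True, info.get("partner"),
                                 info.get("alternative_a"),
                                 info.get("alternative_b")))
    return out


def write_propka_file(path: str | Path, records: list[PkaRecord]) -> None:
    """Write records of one frame in the PROPKA 3.1 summary layout.

    Inverse of :func:`parse_propka` for a single frame; used to build
    synthetic fixtures and for round-trip testing.
    """
    lines = ["propka3.1", "", "SUMMARY OF THIS PREDICTION",
             "     Group      pKa  model-pKa"]
    for r in records:
        res3 = _ONE_TO_THREE[r.residue[0]]
        num = int(r.residue[1:])
        lines.append(f"   {res3} {num:3d} A    {r.pka:5.2f}      {r.pka:5.2f}")
    coupled = [r for r in records if r.coupled]
    if coupled:
        lines.append("-" * 80)
        lines.append("COUPLED RESIDUES")
        seen = set()
        for r in coupled:
            pair = tuple(sorted([r.residue, r.partner]))
            if pair in seen:
                continue
            seen.add(pair)
            mate = next((x for x in coupled if x.residue == r.partner), None)
            res3a, numa = _ONE_TO_THREE[r.residue[0]], int(r.residue[1:])
            res3b, numb = _ONE_TO_THREE[r.partner[0]], int(r.partner[1:])
            lines.append(f"   {res3a} {numa:3d} A coupled to {res3b} {numb:3d} A")
            mate_a = mate.alternative_a if mate else r.alternative_b
            mate_b = mate.alternative_b if mate else r.alternative_a
            lines.append(f"   alternative a: {res3a} {numa:3d} A "
                         f"{r.alternative_a:5.2f}   {res3b} {numb:3d} A "
                         f"{mate_a:5.2f}")
            lines.append(f"   alternative b: {res3a} {numa:3d} A "
                         f"{r.alternative_b:5.2f}   {res3b} {numb:3d} A "
                         f"{mate_b:5.2f}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PkaSummary:
    """Ensemble statistics of one residue's pKa distribution."""

    residue: str
    n_frames: int
    mean: float
    sd: float
    mean_coupling: float | None
    sd_coupling: float | None
    coupling_percent: float
    window_fraction: float
    window: tuple[float, float]
    reaches_window: bool
    histogram_all: tuple[np.ndarray, np.ndarray]
    histogram_alt_a: tuple[np.ndarray, np.ndarray] | None = None
    histogram_alt_b: tuple[np.ndarray, np.ndarray] | None = None


def aggregate(records: list[PkaRecord], window: tuple[float, float] = CRITICAL_WINDOW,
              bins: int = 60, hist_range: tuple[float, float] = (0.0, 14.0),
              window_mass_threshold: float = 0.01) -> dict[str, PkaSummary]:
    """Per-residue ensemble summaries.

    ``reaches_window`` operationalizes "the distribution reaches into
    the critical region" as more than ``window_mass_threshold`` (1% by
    default) of the mass inside ``window``.  Alternative-a/b histograms
    are emitted only when the residue shows any coupling.
    """
    by_res: dict[str, list[PkaRecord]] = {}
    for r in records:
        by_res.setdefault(r.residue, []).append(r)
    out = {}
    for res, recs in by_res.items():
        vals = np.array([r.pka for r in recs])
        coupled = [r for r in recs if r.coupled]
        frac = vals.size and float(((vals >= window[0]) & (vals <= window[1])).mean())
        hist = np.histogram(vals, bins=bins, range=hist_range, density=True)
        if coupled:
            cv = np.array([r.pka for r in coupled])
            alt_a = np.array([r.alternative_a for r in coupled])
            alt_b = np.array([r.alternative_b for r in coupled])
            summary = PkaSummary(
                res, len(recs), float(vals.mean()), float(vals.std()),
                float(cv.mean()), float(cv.std()),
                100.0 * len(coupled) / len(recs), float(frac), window,
                frac > window_mass_threshold,
                hist,
                np.histogram(alt_a, bins=bins, range=hist_range, density=True),
                np.histogram(alt_b, bins=bins, range=hist_range, density=True))
        else:
            summary = PkaSummary(res, len(recs), float(vals.mean()),
                                 float(vals.std()), None, None, 0.0,
                                 float(frac), window,
                                 frac > window_mass_threshold, hist)
        out[res] = summary
    return out


def summary_table(summaries: dict[str, PkaSummary]) -> pd.DataFrame:
    rows = []
    for res, s in summaries.items():
        rows.append({"residue": res, "n_frames": s.n_frames,
                     "mean_pka": s.mean, "sd_pka": s.sd,
                     "mean_pka_coupling": s.mean_coupling,
                     "sd_pka_coupling": s.sd_coupling,
                     "coupling_percent": s.coupling_percent,
                     "window_fraction": s.window_fraction,
                     "reaches_window": s.reaches_window})
    return pd.DataFrame(rows)
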