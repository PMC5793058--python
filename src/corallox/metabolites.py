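"""Eicosanoid peak assignment and radiochromatogram conversion rates.

Peaks from reversed-phase LC runs (radio, UV 235 nm, or negative-mode MS
channels) are identified by comparing retention time and [M-H]- m/z
against a reference table of eicosanoid anchors: arachidonic acid (AA),
the HETE positional isomers (all m/z 319.2, separated only by retention
time), the allene-oxide end products alpha-ketol (335.2) and
cyclopentenone (317.2), and the prostaglandins PGF2a (353.2), PGE2 and
PGD2 (both 351.2).  Substrate conversion is the fraction of total
radiolabelled peak area not attributable to the substrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .errors import ConfigurationError, ContractError, FormatError

Channel = Literal["radio", "uv235", "ms"]

DEFAULT_RT_TOL = 0.2  # min; preserves the 16.8/17.0/17.2/17.4 HETE separations
DEFAULT_MZ_TOL = 0.05  # anchors are printed to one decimal


@dataclass(frozen=True)
class Peak:
    """One chromatographic peak.

    m/z is carried only by MS-channel peaks; radio and UV peaks have
    retention time and area alone.  ``condition`` is free-text metadata
    (e.g. "EDTA") carried through reports untouched.
    """

    rt: float
    area: float
    channel: Channel
    mz: float | None = None
    condition: str | None = None

    def __post_init__(self):
        if self.rt < 0:
            raise ContractError("retention time must be >= 0")
        if self.area < 0:
            raise ContractError("peak area must be >= 0")
        if self.channel not in ("radio", "uv235", "ms"):
            raise ContractError(f"unknown channel {self.channel!r}")
        if self.channel == "ms" and self.mz is None:
            raise ContractError("MS-channel peaks require an m/z")
        if self.channel != "ms" and self.mz is not None:
            raise ContractError(f"{self.channel}-channel peaks carry no m/z")


@dataclass(frozen=True)
class MetaboliteRef:
    """A reference anchor: at least one of retention time / m/z."""

    name: str
    rt: float | None = None
    mz: float | None = None

    def __post_init__(self):
        if self.rt is None and self.mz is None:
            raise ContractError(f"{self.name}: reference needs rt or mz")


#: Printed anchors for the eicosanoids followed in coral incubations.
#: PGD2 has no anchored retention time; it is matched on m/z only and
#: flagged ambiguous against PGE2.  Aldehydes (cHPL products) have no
#: printed anchors and are deliberately absent.
DEFAULT_EICOSANOID_REFS: tuple[MetaboliteRef, ...] = (
    MetaboliteRef("arachidonic acid", rt=19.9),
    MetaboliteRef("8-HETE", rt=17.2, mz=319.2),
    MetaboliteRef("15-HETE", rt=16.8, mz=319.2),
    MetaboliteRef("11-HETE", rt=17.0, mz=319.2),
    MetaboliteRef("5-HETE", rt=17.4, mz=319.2),
    MetaboliteRef("alpha-ketol", mz=335.2),
    MetaboliteRef("cyclopentenone", mz=317.2),
    MetaboliteRef("PGF2a", rt=6.9, mz=353.2),
    MetaboliteRef("PGE2", rt=8.5, mz=351.2),
    MetaboliteRef("PGD2", mz=351.2),
)


@dataclass(frozen=True)
class Assignment:
    peak: Peak
    metabolite: str | None  # None = unassigned
    delta_rt: float | None = None
    delta_mz: float | None = None
    ambiguous: bool = False
    alternatives: tuple[str, ...] = ()


def _match_score(peak: Peak, ref: MetaboliteRef, rt_tol: float, mz_tol: float):
    """(n_shared_fields, normalized distance) if every shared gate passes, else None."""
    deltas = []
    d_rt = d_mz = None
    if ref.rt is not None:
        d_rt = peak.rt - ref.rt
        if abs(d_rt) > rt_tol:
            return None
        deltas.append(abs(d_rt) / rt_tol)
    if ref.mz is not None and peak.mz is not None:
        d_mz = peak.mz - ref.mz
        if abs(d_mz) > mz_tol:
            return None
        deltas.append(abs(d_mz) / mz_tol)
    if not deltas:
        return None
    return len(deltas), sum(deltas) / len(deltas), d_rt, d_mz


def assign_peaks(
    peaks: Sequence[Peak],
    refs: Sequence[MetaboliteRef] = DEFAULT_EICOSANOID_REFS,
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
) -> list[Assignment]:
    """Identify peaks against the reference anchors.

    A reference is a candidate when every field both sides carry (rt,
    m/z) agrees within its tolerance; among candidates the one matching
    more fields wins, then the smallest tolerance-normalized distance.
    Exact score ties, and m/z-only winners that share their m/z with
    another reference (the PGE2/PGD2 situation), are flagged ambiguous
    with the alternatives listed.
    """
    if not refs:
        raise ConfigurationError("empty metabolite reference table")
    if rt_tol <= 0 or mz_tol <= 0:
        raise ContractError("tolerances must be positive")
    out = []
    for peak in peaks:
        scored = []
        for ref in refs:
            s = _match_score(peak, ref, rt_tol, mz_tol)
            if s is not None:
                scored.append((s[0], s[1], ref, s[2], s[3]))
        if not scored:
            out.append(Assignment(peak, None))
            continue
        scored.sort(key=lambda t: (-t[0], t[1]))
        n_shared, dist, ref, d_rt, d_mz = scored[0]
        alternatives = []
        ambiguous = False
        for ns, dst, other, _, _ in scored[1:]:
            if ns != n_shared:
                continue
            same_mz_anchor = (
                ref.mz is not None
                and other.mz is not None
                and abs(ref.mz - other.mz) <= 1e-9
            )
            # exact score ties, and same-m/z isomers whose rt also falls in
            # tolerance (the HETE situation), are not confidently resolvable
            if abs(dst - dist) <= 1e-9 or same_mz_anchor:
                ambiguous = True
                alternatives.append(other.name)
        if n_shared == 1 and d_mz is not None:
            # matched on m/z alone: other references with the same anchor
            # m/z are indistinguishable without retention-time evidence
            for other in refs:
                if other.name != ref.name and other.mz is not None and peak.mz is not None:
                    if abs(peak.mz - other.mz) <= mz_tol and other.name not in alternatives:
                        ambiguous = True
                        alternatives.append(other.name)
        out.append(
            Assignment(peak, ref.name, d_rt, d_mz, ambiguous, tuple(alternatives))
        )
    return out


def conversion_rate(
    peaks: Sequence[Peak],
    substrate: str = "arachidonic acid",
    refs: Sequence[MetaboliteRef] = DEFAULT_EICOSANOID_REFS,
    rt_tol: float = DEFAULT_RT_TOL,
) -> float:
    """Percent of total radio peak area converted away from the substrate.

    rate = 100 * (area of radio peaks outside the substrate's retention
    window) / (total radio peak area).  A substrate-only chromatogram
    gives 0.0 (no conversion).
    """
    radio = [p for p in peaks if p.channel == "radio"]
    if not radio:
        raise ContractError("conversion_rate requires at least one radio-channel peak")
    ref = next((r for r in refs if r.name == substrate), None)
    if ref is None or ref.rt is None:
        raise ConfigurationError(f"substrate {substrate!r} not in reference table with rt")
    total = sum(p.area for p in radio)
    if total <= 0:
        raise ContractError("total radio peak area is zero; conversion rate undefined")
    product = sum(p.area for p in radio if abs(p.rt - ref.rt) > rt_tol)
    return 100.0 * product / total


def read_peak_table(path) -> list[Peak]:
    """Read a peak CSV with columns rt_min, mz, area, channel[, condition]."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"unreadable peak CSV ({exc})", path=path) from exc
    required = {"rt_min", "area", "channel"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing columns {sorted(missing)}", path=path)
    peaks = []
    for _, row in df.iterrows():
        mz = row.get("mz")
        mz = None if mz is None or (isinstance(mz, float) and math.isnan(mz)) else float(mz)
        cond = row.get("condition")
        cond = None if cond is None or (isinstance(cond, float) and math.isnan(cond)) else str(cond)
        peaks.append(
            Peak(
                rt=float(row["rt_min"]),
                area=float(row["area"]),
                channel=str(row["channel"]),
                mz=mz,
                condition=cond,
            )
        )
    return peaks


def write_peak_table(peaks: Sequence[Peak], path) -> None:
    df = pd.DataFrame(
        {
            "rt_min": [p.rt for p in peaks],
            "mz": [p.mz for p in peaks],
            "area": [p.area for p in peaks],
            "channel": [p.channel for p in peaks],
            "condition": [p.condition for p in peaks],
        }
    )
    df.to_csv(path, index=False)
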