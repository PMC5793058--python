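"""Synthetic sequences and peak tables with planted ground truth.

Every pipeline stage is testable offline against data whose true labels
are known by construction.  The generator emits:

* a 1066-aa pseudo-reference fusion protein with the canonical feature
  layout planted at the published coordinates — WLLAK anchor at 737,
  iron ligands His757/His762/His943/Asn947, terminal Ile1066, C-terminal
  PNGTAI motif, AOS tetrad Thr66/His67/Arg349/Tyr353, and a declared
  Coffa-determinant site (position 773 by default; the real coordinate
  in reference numbering is not published, so the layout declares one);
* panels of fusion / stand-alone LOX / partial-core / COX-like / decoy
  sequences derived from that layout, with per-sequence truth records;
* peak tables jittered around the eicosanoid anchors.

Background residues are drawn uniformly over the 20 amino acids; motif
and residue planting dominates every detection step, so compositional
realism is deliberately not modelled.  All outputs are deterministic
functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError
from .metabolites import DEFAULT_EICOSANOID_REFS, MetaboliteRef, Peak
from .seqio import ProteinCandidate, SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ClassName = Literal["AOS_LOX_fusion", "LOX_full", "LOX_partial", "COX_like", "decoy"]

DEFAULT_CLASS_MIX: dict[str, float] = {
    "AOS_LOX_fusion": 0.30,
    "LOX_full": 0.25,
    "LOX_partial": 0.25,
    "COX_like": 0.10,
    "decoy": 0.10,
}


@dataclass(frozen=True)
class ReferenceLayout:
    """Planted coordinates of the pseudo-reference fusion protein."""

    length: int = 1066
    aos_domain: tuple[int, int] = (1, 373)
    lox_domain: tuple[int, int] = (374, 1066)
    aos_residues: tuple[tuple[int, str], ...] = ((66, "T"), (67, "H"), (349, "R"), (353, "Y"))
    wllak_start: int = 737
    coffa_pos: int = 773
    iron_ligands: tuple[tuple[int, str], ...] = (
        (757, "H"),
        (762, "H"),
        (943, "H"),
        (947, "N"),
    )
    yrdd_start: int = 900
    haavn_start: int = 960
    cterm_motif: str = "PNGTAI"  # ends at `length`; final residue overridden to I

    def planted_positions(self) -> dict[int, str]:
        """1-based position -> planted residue; raises on overlap."""
        planted: dict[int, str] = {}

        def put(pos: int, aa: str):
            if pos in planted and planted[pos] != aa:
                raise ConfigurationError(
                    f"reference layout conflict at position {pos}: "
                    f"{planted[pos]} vs {aa}"
                )
            if not 1 <= pos <= self.length:
                raise ConfigurationError(f"planted position {pos} outside layout")
            planted[pos] = aa

        for i, aa in enumerate("WLLAK"):
            put(self.wllak_start + i, aa)
        for i, aa in enumerate("YRDD"):
            put(self.yrdd_start + i, aa)
        for i, aa in enumerate("HAAVN"):
            put(self.haavn_start + i, aa)
        start = self.length - len(self.cterm_motif) + 1
        for i, aa in enumerate(self.cterm_motif):
            put(start + i, aa)
        put(self.length, "I")  # terminal iron-coordinating Ile
        for pos, aa in self.iron_ligands:
            put(pos, aa)
        for pos, aa in self.aos_residues:
            put(pos, aa)
        put(self.coffa_pos, "G")  # default determinant: Gly (R-stereospecific)
        return planted


@dataclass
class SynthConfig:
    """Panel-generation settings.

    class_mix proportions must sum to 1; counts are rounded by largest
    remainder so every class count is within one of ``mix * n``.
    ``mutation_spec`` plants substitutions at rule sites: tuples of
    (role, reference position, replacement residue, probability).
    ``background_divergence`` is the per-site substitution rate applied
    to non-planted positions of each emitted sequence, giving the panel
    a realistic identity spread without disturbing planted features.
    ``coffa_mix`` is the distribution the planted determinant residue is
    drawn from (Gly/Ala predict R/S; Ile/Phe/Val mimic the observed
    indeterminate coral variants).
    """

    seed: int = 0
    n_sequences: int = 200
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    mutation_spec: list[tuple[str, int, str, float]] = field(default_factory=list)
    background_divergence: float = 0.10
    coffa_mix: dict[str, float] = field(
        default_factory=lambda: {"G": 0.6, "A": 0.3, "I": 0.04, "F": 0.03, "V": 0.03}
    )
    partial_length_range: tuple[int, int] = (330, 340)
    decoy_length_range: tuple[int, int] = (300, 900)
    cox_length: int = 600
    cox_divergence: float = 0.30
    layout: ReferenceLayout = field(default_factory=ReferenceLayout)

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("class_mix proportions must sum to 1")
        unknown = set(self.class_mix) - set(DEFAULT_CLASS_MIX)
        if unknown:
            raise ConfigurationError(f"unknown classes in class_mix: {sorted(unknown)}")


@dataclass
class TruthRecord:
    """Ground truth for one generated sequence."""

    seq_id: str
    architecture: str
    completeness: str | None
    stereospecificity: str
    predicted_active: bool
    substitutions: tuple[str, ...] = ()
    fragment_span: tuple[int, int] | None = None


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_pseudo_reference(config: SynthConfig | None = None) -> ProteinCandidate:
    """The synthetic stand-in for the canonical fusion reference.

    Deterministic under the config seed; all layout features planted on
    a uniform random background.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    layout = config.layout
    planted = layout.planted_positions()
    residues = list(_random_protein(rng, layout.length))
    for pos, aa in planted.items():
        residues[pos - 1] = aa
    return ProteinCandidate("pseudo_reference", "".join(residues), "as_is")


def make_cox_reference(config: SynthConfig | None = None) -> ProteinCandidate:
    """A synthetic cyclooxygenase-like reference (random, WLLAK-free)."""
    config = config or SynthConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    while True:
        seq = _random_protein(rng, config.cox_length)
        if "WLLAK" not in seq:
            return ProteinCandidate("synthetic_cox_reference", seq, "as_is")


def _diverge(
    rng: np.random.Generator, residues: str, keep: set[int], rate: float
) -> str:
    """Substitute non-protected positions at the given per-site rate."""
    out = list(residues)
    for i in range(len(out)):
        if (i + 1) in keep:
            continue
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _stereo_of(coffa_aa: str) -> str:
    return {"G": "R", "A": "S"}.get(coffa_aa, "indeterminate")


def generate_panel(
    config: SynthConfig | None = None,
) -> tuple[list[SeqRecord], list[TruthRecord]]:
    """A labelled sequence panel plus one truth record per sequence.

    Fusions are full-length (1066 aa) diverged copies of the reference
    layout; stand-alone LOXs are the LOX-domain slice (693 aa); partial
    cores run from (at most 10 residues before) the WLLAK anchor to the
    C-terminus; COX-like sequences are diverged copies of the synthetic
    COX reference; decoys are unrelated random proteins.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    layout = config.layout
    planted = layout.planted_positions()
    reference = make_pseudo_reference(config)
    cox_reference = make_cox_reference(config)

    # largest-remainder apportionment of class counts
    order = ["AOS_LOX_fusion", "LOX_full", "LOX_partial", "COX_like", "decoy"]
    raw = {c: config.class_mix.get(c, 0.0) * config.n_sequences for c in order}
    counts = {c: int(np.floor(raw[c])) for c in order}
    short = config.n_sequences - sum(counts.values())
    for c in sorted(order, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1

    coffa_aas = list(config.coffa_mix)
    coffa_p = np.array([config.coffa_mix[a] for a in coffa_aas], dtype=float)
    coffa_p /= coffa_p.sum()

    records: list[SeqRecord] = []
    truths: list[TruthRecord] = []
    idx = 0
    for cls in order:
        for _ in range(counts[cls]):
            idx += 1
            seq_id = f"syn{idx:04d}_{cls}"
            if cls in ("AOS_LOX_fusion", "LOX_full", "LOX_partial"):
                site_residues = dict(planted)
                substitutions: list[str] = []
                coffa_aa = str(rng.choice(coffa_aas, p=coffa_p))
                site_residues[layout.coffa_pos] = coffa_aa
                for role, pos, new_aa, prob in config.mutation_spec:
                    if rng.random() < prob and pos in site_residues:
                        site_residues[pos] = new_aa
                        substitutions.append(f"{role}@{pos}:{new_aa}")
                full = list(
                    _diverge(
                        rng,
                        reference.residues,
                        set(site_residues),
                        config.background_divergence,
                    )
                )
                for pos, aa in site_residues.items():
                    full[pos - 1] = aa
                full = "".join(full)
                iron = dict(layout.iron_ligands)
                active = all(
                    site_residues[pos] == aa for pos, aa in iron.items()
                ) and site_residues[layout.length] == "I"
                stereo = _stereo_of(coffa_aa)
                if cls == "AOS_LOX_fusion":
                    residues = full
                    completeness = "full_length"
                    span = (1, layout.length)
                elif cls == "LOX_full":
                    lo, hi = layout.lox_domain
                    residues = full[lo - 1 : hi]
                    completeness = "full_length"
                    span = layout.lox_domain
                else:
                    length = int(
                        rng.integers(
                            config.partial_length_range[0],
                            config.partial_length_range[1] + 1,
                        )
                    )
                    start = layout.length - length + 1
                    residues = full[start - 1 :]
                    completeness = "partial"
                    span = (start, layout.length)
                records.append(SeqRecord(seq_id, residues, "protein"))
                truths.append(
                    TruthRecord(
                        seq_id,
                        "LOX" if cls != "AOS_LOX_fusion" else "AOS_LOX_fusion",
                        completeness,
                        stereo,
                        active,
                        tuple(substitutions),
                        span,
                    )
                )
            elif cls == "COX_like":
                residues = _diverge(
                    rng, cox_reference.residues, set(), config.cox_divergence
                )
                if "WLLAK" in residues:  # vanishingly rare; keep decoys clean
                    residues = residues.replace("WLLAK", "WLLAA")
                records.append(SeqRecord(seq_id, residues, "protein"))
                truths.append(
                    TruthRecord(seq_id, "COX_like", None, "indeterminate", False)
                )
            else:  # decoy
                length = int(
                    rng.integers(
                        config.decoy_length_range[0], config.decoy_length_range[1] + 1
                    )
                )
                residues = _random_protein(rng, length)
                if "WLLAK" in residues:
                    residues = residues.replace("WLLAK", "WLLAA")
                records.append(SeqRecord(seq_id, residues, "protein"))
                truths.append(
                    TruthRecord(seq_id, "non_dioxygenase", None, "indeterminate", False)
                )
    return records, truths


def truth_table(truths: Sequence[TruthRecord]):
    """Truth records as a pandas DataFrame (for TSV round trips)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "seq_id": [t.seq_id for t in truths],
            "architecture": [t.architecture for t in truths],
            "completeness": [t.completeness for t in truths],
            "stereospecificity": [t.stereospecificity for t in truths],
            "predicted_active": [t.predicted_active for t in truths],
            "substitutions": [";".join(t.substitutions) for t in truths],
        }
    )


#: rt window used for metabolites whose reference carries no anchored rt
#: (alpha-ketol, cyclopentenone, PGD2): a quiet mid-chromatogram region
#: between the prostaglandins (<= 8.5 min) and the HETEs (>= 16.8 min).
UNANCHORED_RT_WINDOW = (10.0, 15.0)


def generate_peak_table(
    truth: Sequence[tuple[str, float]],
    noise: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    channel: str = "ms",
    refs: Sequence[MetaboliteRef] = DEFAULT_EICOSANOID_REFS,
    condition: str | None = None,
) -> list[Peak]:
    """One peak per (metabolite, area) truth entry, jittered by centred noise.

    References without an anchored retention time get one drawn from
    ``UNANCHORED_RT_WINDOW``.  Radio/UV channels drop the m/z, matching
    what those detectors report.
    """
    by_name = {r.name: r for r in refs}
    sigma_rt, sigma_mz = noise
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    peaks = []
    for name, area in truth:
        ref = by_name.get(name)
        if ref is None:
            raise ConfigurationError(f"unknown metabolite {name!r} in peak truth")
        rt = ref.rt if ref.rt is not None else float(rng.uniform(*UNANCHORED_RT_WINDOW))
        rt = max(0.0, rt + (rng.normal(0.0, sigma_rt) if sigma_rt > 0 else 0.0))
        if channel == "ms":
            if ref.mz is None:
                raise ConfigurationError(
                    f"{name!r} has no reference m/z; cannot emit an MS peak"
                )
            mz = ref.mz + (rng.normal(0.0, sigma_mz) if sigma_mz > 0 else 0.0)
            peaks.append(Peak(rt, area, "ms", mz, condition))
        else:
            peaks.append(Peak(rt, area, channel, None, condition))  # type: ignore[arg-type]
    return peaks
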