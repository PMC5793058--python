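"""End-to-end orchestration: annotate, tree, and peak runs.

Each run reads its inputs, applies the library stages in a fixed order,
and writes deterministic reports (TSV/CSV/JSON/Newick).  A malformed
individual sequence becomes an error row; only unreadable inputs abort
a run.  Timestamps are confined to the log, never to data outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .anchormap import ResidueRule, default_rule_table
from .classify import (
    Classification,
    ClassifyConfig,
    PREDICTION_CAVEAT,
    ReferenceSet,
    classify_sequence,
)
from .errors import ConfigurationError, ContractError, CoralloxError, FormatError
from .metabolites import (
    DEFAULT_EICOSANOID_REFS,
    DEFAULT_MZ_TOL,
    DEFAULT_RT_TOL,
    assign_peaks,
    conversion_rate,
    read_peak_table,
)
from .motifs import DEFAULT_MOTIFS, MotifDef, trim_core
from .phylo import identity_matrix, nj_tree, write_newick
from .seqio import ProteinCandidate, SeqRecord, read_fasta, read_genbank, to_protein

logger = logging.getLogger("corallox")


@dataclass
class RunConfig:
    """Configuration for a pipeline run.

    The LOX reference is mandatory for annotation; without a COX
    reference no COX_like verdict can be produced (sequences failing the
    LOX filter then fall through to non_dioxygenase); without a Coffa
    position no stereospecificity prediction is made.
    """

    input_path: str | Path | None = None
    lox_reference: ProteinCandidate | None = None
    cox_reference: ProteinCandidate | None = None
    coffa_pos: int | None = None
    motif_defs: Sequence[MotifDef] = DEFAULT_MOTIFS
    rules: Sequence[ResidueRule] | None = None
    classify_config: ClassifyConfig = field(default_factory=ClassifyConfig)
    tree_mode: Literal["core", "full"] = "core"
    identity_cut: float = 60.0
    rt_tol: float = DEFAULT_RT_TOL
    mz_tol: float = DEFAULT_MZ_TOL
    min_orf_aa: int = 100
    out_dir: str | Path | None = None
    seed: int = 0

    def resolved_rules(self) -> list[ResidueRule]:
        if self.rules is not None:
            return list(self.rules)
        return default_rule_table(self.coffa_pos)


def load_sequences(path: str | Path) -> list[SeqRecord]:
    """Read FASTA or GenBank based on content sniffing."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(256).lstrip()
    if head.startswith("LOCUS"):
        return read_genbank(path)
    return read_fasta(path)


@dataclass
class AnnotateResult:
    classifications: list[Classification]
    report: pd.DataFrame
    errors: list[tuple[str, str]]  # (seq_id, message)


def _report_frame(classifications: Sequence[Classification], errors) -> pd.DataFrame:
    rows = []
    for c in classifications:
        rows.append(
            {
                "seq_id": c.seq_id,
                "architecture": c.architecture,
                "completeness": c.completeness if c.completeness is not None else "NA",
                "coffa_predicted_stereo": c.stereospecificity,
                "predicted_active": c.predicted_active,
                "failed_rules": ";".join(c.failed_rules()),
                "notes": "|".join(c.notes),
                "status": "ok",
                "caveat": c.caveat,
            }
        )
    for seq_id, message in errors:
        rows.append(
            {
                "seq_id": seq_id,
                "architecture": "NA",
                "completeness": "NA",
                "coffa_predicted_stereo": "NA",
                "predicted_active": "NA",
                "failed_rules": "",
                "notes": message,
                "status": "error",
                "caveat": PREDICTION_CAVEAT,
            }
        )
    return pd.DataFrame(rows)


def run_annotate(
    config: RunConfig, records: Sequence[SeqRecord] | None = None
) -> AnnotateResult:
    """Classify every candidate in the input; one report row per sequence.

    Rows keep input order; repeated runs on identical inputs produce
    byte-identical reports.
    """
    if config.lox_reference is None:
        raise ConfigurationError("annotation requires a LOX-numbering reference")
    if records is None:
        if config.input_path is None:
            raise ConfigurationError("no input sequences supplied")
        records = load_sequences(config.input_path)
    if not records:
        raise FormatError("no sequences in input")
    refs = ReferenceSet(config.lox_reference, config.cox_reference)
    rules = config.resolved_rules()
    classifications: list[Classification] = []
    errors: list[tuple[str, str]] = []
    n_translated = 0
    for rec in records:
        try:
            candidates = to_protein(rec, min_length=config.min_orf_aa)
            if not candidates:
                errors.append((rec.id, "no ORF of sufficient length"))
                continue
            for cand in candidates:
                n_translated += 1
                classifications.append(
                    classify_sequence(
                        cand, refs, rules, config.classify_config, config.motif_defs
                    )
                )
        except CoralloxError as exc:
            errors.append((rec.id, str(exc)))
    counts = pd.Series([c.architecture for c in classifications]).value_counts()
    logger.info(
        "annotate: %d records in, %d candidates translated, verdicts: %s",
        len(records),
        n_translated,
        counts.to_dict(),
    )
    report = _report_frame(classifications, errors)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.tsv", sep="\t", index=False)
        evidence = [
            {
                "seq_id": c.seq_id,
                "architecture": c.architecture,
                "completeness": c.completeness,
                "coffa_predicted_stereo": c.stereospecificity,
                "predicted_active": c.predicted_active,
                "lox_checks": [
                    {
                        "ref_pos": chk.rule.ref_pos,
                        "role": chk.rule.role,
                        "query_pos": chk.query_pos,
                        "observed": chk.observed,
                        "status": chk.status,
                    }
                    for chk in c.lox_checks
                ],
                "aos_checks": [
                    {
                        "ref_pos": chk.rule.ref_pos,
                        "role": chk.rule.role,
                        "query_pos": chk.query_pos,
                        "observed": chk.observed,
                        "status": chk.status,
                    }
                    for chk in c.aos_checks
                ],
                "notes": c.notes,
                "caveat": c.caveat,
            }
            for c in classifications
        ]
        (out / "report.json").write_text(json.dumps(evidence, indent=2) + "\n")
    return AnnotateResult(classifications, report, errors)


@dataclass
class TreeResult:
    labels: list[str]
    matrix: "pd.DataFrame"
    newick: str


def run_tree(
    config: RunConfig,
    records: Sequence[SeqRecord] | None = None,
    annotate_result: AnnotateResult | None = None,
) -> TreeResult:
    """Identity matrix + NJ tree over the classified LOX/AOS-LOX sequences.

    In "core" mode every eligible sequence is trimmed from its WLLAK
    anchor to the C-terminus before alignment (the partial-sequence
    protocol); "full" mode uses complete sequences.
    """
    result = annotate_result or run_annotate(
        RunConfig(**{**config.__dict__, "out_dir": None}), records
    )
    if records is None:
        records = load_sequences(config.input_path)
    by_id = {}
    for rec in records:
        for cand in to_protein(rec, min_length=config.min_orf_aa):
            by_id.setdefault(cand.parent_id, cand)
    eligible = [
        c for c in result.classifications if c.architecture in ("LOX", "AOS_LOX_fusion")
    ]
    if len(eligible) < 3:
        raise ContractError(
            f"tree construction needs >= 3 LOX/AOS-LOX sequences, found {len(eligible)}"
        )
    proteins = []
    labels = []
    for c in eligible:
        cand = by_id[c.seq_id]
        if config.tree_mode == "core":
            core = trim_core(cand, config.motif_defs)
            cand = ProteinCandidate(c.seq_id, core.residues, "as_is")
        proteins.append(cand)
        labels.append(c.seq_id)
    m = identity_matrix(proteins, config.classify_config.align_params, labels)
    tree = nj_tree(m)
    newick = write_newick(tree)
    frame = pd.DataFrame(m.values, index=labels, columns=labels)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        m.to_tsv(out / "identity_matrix.tsv")
        (out / "tree.nwk").write_text(newick + "\n")
    return TreeResult(labels, frame, newick)


@dataclass
class PeaksResult:
    assignments: pd.DataFrame
    conversion: pd.DataFrame  # one row per condition; rate NaN when unavailable


def run_peaks(config: RunConfig, peaks=None) -> PeaksResult:
    """Assign peaks and compute per-condition radiochromatogram conversion."""
    if peaks is None:
        if config.input_path is None:
            raise ConfigurationError("no peak table supplied")
        peaks = read_peak_table(config.input_path)
    assignments = assign_peaks(peaks, DEFAULT_EICOSANOID_REFS, config.rt_tol, config.mz_tol)
    rows = [
        {
            "rt_min": a.peak.rt,
            "mz": a.peak.mz,
            "area": a.peak.area,
            "channel": a.peak.channel,
            "condition": a.peak.condition,
            "metabolite": a.metabolite if a.metabolite else "unassigned",
            "delta_rt": a.delta_rt,
            "delta_mz": a.delta_mz,
            "ambiguous": a.ambiguous,
            "alternatives": ";".join(a.alternatives),
        }
        for a in assignments
    ]
    adf = pd.DataFrame(rows)
    conv_rows = []
    conditions = sorted({p.condition for p in peaks}, key=lambda c: (c is not None, c or ""))
    for cond in conditions:
        sub = [p for p in peaks if p.condition == cond]
        radio = [p for p in sub if p.channel == "radio"]
        if radio:
            rate = conversion_rate(sub, rt_tol=config.rt_tol)
            conv_rows.append(
                {"condition": cond or "", "conversion_rate_pct": rate, "n_radio_peaks": len(radio)}
            )
        else:
            conv_rows.append(
                {"condition": cond or "", "conversion_rate_pct": float("nan"), "n_radio_peaks": 0}
            )
    cdf = pd.DataFrame(conv_rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        adf.to_csv(out / "assignments.csv", index=False)
        cdf.to_csv(out / "conversion.csv", index=False)
    return PeaksResult(adf, cdf)
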