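"""End-to-end study orchestration.

One config drives the full analysis: QTY conversion and characterization of
every annotated subunit, per-subunit Cα superposition of predicted models
against the reference structure, hydrophobic-surface fractions, and the
complex-level DockQ report. Stages are independent — a failure in one is
recorded and the others still run — and the report carries provenance hashes
of every input so identical inputs yield identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from . import interface as iq
from . import sasa as sa
from . import sequence as sq
from . import structure as st

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Configuration for one study run. Paths are resolved relative to the
    config file's directory when loaded from YAML."""

    fasta: str | None = None
    segments: str | None = None
    reference_structure: str | None = None
    model_structures: Mapping[str, str] = field(default_factory=dict)  # subunit -> path
    complex_model: str | None = None
    chain_map: Mapping[str, str] = field(default_factory=dict)  # subunit/ref chain -> model chain
    run_sequences: bool = True
    run_superposition: bool = True
    run_hydrophobicity: bool = True
    run_interface_scoring: bool = True
    outlier_rejection: tuple[float, int] | None = None
    contact_cutoff: float = iq.CONTACT_CUTOFF
    interface_cutoff: float = iq.INTERFACE_CUTOFF
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(p):
            return str((base / p).resolve()) if p else None

        rej = raw.get("outlier_rejection")
        return cls(
            fasta=resolve(raw.get("fasta")),
            segments=resolve(raw.get("segments")),
            reference_structure=resolve(raw.get("reference_structure")),
            model_structures={
                k: resolve(v) for k, v in (raw.get("model_structures") or {}).items()
            },
            complex_model=resolve(raw.get("complex_model")),
            chain_map=dict(raw.get("chain_map") or {}),
            run_sequences=raw.get("run_sequences", True),
            run_superposition=raw.get("run_superposition", True),
            run_hydrophobicity=raw.get("run_hydrophobicity", True),
            run_interface_scoring=raw.get("run_interface_scoring", True),
            outlier_rejection=tuple(rej) if rej else None,
            contact_cutoff=raw.get("contact_cutoff", iq.CONTACT_CUTOFF),
            interface_cutoff=raw.get("interface_cutoff", iq.INTERFACE_CUTOFF),
            output_dir=resolve(raw.get("output_dir")),
        )

    def to_dict(self) -> dict:
        return {
            "fasta": self.fasta,
            "segments": self.segments,
            "reference_structure": self.reference_structure,
            "model_structures": dict(self.model_structures),
            "complex_model": self.complex_model,
            "chain_map": dict(self.chain_map),
            "run_sequences": self.run_sequences,
            "run_superposition": self.run_superposition,
            "run_hydrophobicity": self.run_hydrophobicity,
            "run_interface_scoring": self.run_interface_scoring,
            "outlier_rejection": list(self.outlier_rejection) if self.outlier_rejection else None,
            "contact_cutoff": self.contact_cutoff,
            "interface_cutoff": self.interface_cutoff,
            "output_dir": self.output_dir,
        }


@dataclass
class StudyReport:
    characteristics: Any = None  # DataFrame: per-subunit pI/MW/variation (+ RMSD)
    superpositions: dict[str, st.SuperpositionResult] = field(default_factory=dict)
    hydrophobic_fractions: dict[str, float] = field(default_factory=dict)
    interface_report: iq.ComplexScoreReport | None = None
    provenance: dict[str, str] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload: dict[str, Any] = {
            "provenance": self.provenance,
            "failures": self.failures,
            "hydrophobic_fractions": {
                k: round(v, 4) for k, v in self.hydrophobic_fractions.items()
            },
        }
        if self.characteristics is not None:
            payload["characteristics"] = self.characteristics.to_dict(orient="records")
        if self.superpositions:
            payload["rmsd"] = {
                k: {"rmsd": round(v.rmsd, 3), "n_pairs": v.n_pairs,
                    "n_rejected": len(v.rejected)}
                for k, v in self.superpositions.items()
            }
        if self.interface_report is not None and self.interface_report.n_interfaces:
            payload["interface_summary"] = self.interface_report.summary()
        return json.dumps(payload, indent=2, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Pre-flight diagnostics: missing files, missing chains, length mismatches."""
    issues: list[str] = []
    for label, path in [
        ("fasta", config.fasta),
        ("segments", config.segments),
        ("reference_structure", config.reference_structure),
        ("complex_model", config.complex_model),
        *[(f"model[{k}]", v) for k, v in config.model_structures.items()],
    ]:
        if path and not Path(path).exists():
            issues.append(f"{label}: file not found: {path}")

    records = None
    if config.fasta and Path(config.fasta).exists():
        records = {rid: seq for rid, seq, _ in sq.read_fasta(config.fasta)}
        if config.segments and Path(config.segments).exists():
            segs = sq.read_segments_tsv(config.segments)
            for rid in records:
                if rid not in segs:
                    issues.append(f"sequence {rid}: no TM segments annotated")
            for rid in segs:
                if rid not in records:
                    issues.append(f"segments for unknown sequence {rid}")

    if config.complex_model and config.reference_structure:
        try:
            ref = st.read_structure(config.reference_structure, source="cryoem_reference")
            mod = st.read_structure(config.complex_model)
            mod_ids = set(mod.chain_ids())
            for ref_chain, mod_chain in (config.chain_map or {}).items():
                if ref_chain not in set(ref.chain_ids()):
                    issues.append(f"chain_map: chain {ref_chain} absent from reference")
                if mod_chain not in mod_ids:
                    issues.append(f"chain_map: chain {mod_chain} absent from model")
            if records:
                for cid in ref.chain_ids():
                    if cid in records and len(ref.chain(cid)) > len(records[cid]):
                        issues.append(
                            f"chain {cid}: structure has {len(ref.chain(cid))} residues "
                            f"but sequence only {len(records[cid])}"
                        )
        except (ValueError, KeyError) as exc:
            issues.append(str(exc))
    return issues


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Run every enabled stage; failures are recorded, not propagated."""
    report = StudyReport()
    for label, path in [
        ("fasta", config.fasta),
        ("segments", config.segments),
        ("reference_structure", config.reference_structure),
        ("complex_model", config.complex_model),
        *[(f"model[{k}]", v) for k, v in config.model_structures.items()],
    ]:
        if path and Path(path).exists():
            report.provenance[label] = _sha256(path)

    qty_results: dict[str, sq.QTYResult] = {}
    if config.run_sequences and config.fasta:
        try:
            segs = sq.read_segments_tsv(config.segments) if config.segments else {}
            for rid, seq, desc in sq.read_fasta(config.fasta):
                record = sq.ProteinRecord(rid, seq, tuple(segs.get(rid, ())), desc)
                scope = "tm_only" if record.tm_segments else "whole_sequence"
                qty_results[rid] = sq.apply_qty_code(record, scope=scope)
            report.characteristics = sq.characteristics_table(qty_results.values())
        except Exception as exc:  # stage isolation
            report.failures["sequences"] = str(exc)

    reference = None
    if config.reference_structure:
        try:
            reference = st.read_structure(config.reference_structure, source="cryoem_reference")
        except Exception as exc:
            report.failures["reference_structure"] = str(exc)

    if config.run_superposition and reference is not None and config.model_structures:
        for subunit, path in config.model_structures.items():
            try:
                model = st.read_structure(path)
                ref_chain = subunit if subunit in reference.chain_ids() else None
                if ref_chain is None and subunit in config.chain_map:
                    ref_chain = subunit
                chain_map = None
                if ref_chain is not None:
                    model_chain = config.chain_map.get(subunit, model.chain_ids()[0])
                    chain_map = [(ref_chain, model_chain)]
                corr = st.build_correspondence(reference, model, chain_map)
                report.superpositions[subunit] = st.kabsch_superpose(
                    corr, reference, model, outlier_rejection=config.outlier_rejection
                )
            except Exception as exc:
                report.failures[f"superpose[{subunit}]"] = str(exc)
        if report.characteristics is not None and report.superpositions:
            report.characteristics["rmsd"] = [
                round(report.superpositions[rid].rmsd, 3)
                if rid in report.superpositions else None
                for rid in report.characteristics["id"]
            ]

    if config.run_hydrophobicity and reference is not None:
        try:
            surf = sa.shrake_rupley_sasa(reference)
            report.hydrophobic_fractions["reference"] = sa.hydrophobic_fraction(surf)
        except Exception as exc:
            report.failures["hydrophobicity[reference]"] = str(exc)
    if config.run_hydrophobicity and config.complex_model:
        try:
            model = st.read_structure(config.complex_model)
            surf = sa.shrake_rupley_sasa(model)
            report.hydrophobic_fractions["model"] = sa.hydrophobic_fraction(surf)
        except Exception as exc:
            report.failures["hydrophobicity[model]"] = str(exc)

    if config.run_interface_scoring and reference is not None and config.complex_model:
        try:
            model = st.read_structure(config.complex_model)
            report.interface_report = iq.score_complex(
                reference,
                model,
                chain_map=config.chain_map or None,
                contact_cutoff=config.contact_cutoff,
                interface_cutoff=config.interface_cutoff,
            )
        except Exception as exc:
            report.failures["interface_scoring"] = str(exc)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        if report.characteristics is not None:
            report.characteristics.to_csv(out / "characteristics.tsv", sep="\t", index=False)
        if report.superpositions:
            st.rmsd_report(report.superpositions).to_csv(
                out / "rmsd_report.tsv", sep="\t", index=False
            )
        if report.interface_report is not None and report.interface_report.n_interfaces:
            report.interface_report.to_frame().to_csv(
                out / "interfaces.tsv", sep="\t", index=False
            )
    return report
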