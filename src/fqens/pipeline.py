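"""End-to-end runs: ensemble analysis, free-vs-bound comparison, interface tables.

Everything here is a thin, deterministic orchestration of the library
modules: profiles -> labels -> summary (plus an optional density grid), the
class-by-class comparison of two ensembles, and a per-complex buried
interface table. Reports echo every tunable so a run is reproducible from
its own output.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .classify import (
    DEFAULT_CONTACT_CUTOFF_Q,
    ClassDelta,
    ConformerLabel,
    EnsembleSummary,
    StackingCriteria,
    compare_ensembles,
    labels_from_profiles,
)
from .density import DEFAULT_GRID_SPACING, DEFAULT_ISO_LEVELS, accumulate_density
from .geometry import DEFAULT_CONTACT_CUTOFF, ConformerProfile, profile_conformer
from .io import read_models, resolve_moieties, write_grid
from .model import MolecularModel, MoietyMap
from .sasa import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE_RADIUS,
    InterfaceResult,
    buried_interface,
    moiety_burial,
)

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "run_ensemble_analysis",
    "run_comparison",
    "run_interface_table",
    "profiles_to_frame",
]


@dataclass
class RunConfig:
    """All tunables of an ensemble run; echoed verbatim into every report."""

    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF  # A
    contact_cutoff_q: int = DEFAULT_CONTACT_CUTOFF_Q
    criteria: StackingCriteria = field(default_factory=StackingCriteria)
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_sphere_points: int = DEFAULT_N_POINTS
    grid_spacing: float = DEFAULT_GRID_SPACING
    iso_levels: tuple[float, ...] = DEFAULT_ISO_LEVELS
    seed: int = 0

    def echo(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["criteria"] = dataclasses.asdict(self.criteria)
        return d


def profiles_to_frame(profiles: Sequence[ConformerProfile],
                      labels: Sequence[ConformerLabel] | None = None) -> pd.DataFrame:
    """Per-conformer table behind the Q/d histograms and scatter plots."""
    rows = []
    lab_iter = iter(labels) if labels is not None else None
    for p in profiles:
        row: dict[str, Any] = {"model_index": p.model_index, "incomplete": not p.complete}
        if p.complete:
            row.update(
                q_xq=p.contacts.q_xq, q_pq=p.contacts.q_pq, q_tq=p.contacts.q_tq,
                d_xq=p.geometry.d_xq, d_pq=p.geometry.d_pq,
                angle_xq=p.geometry.angle_xq, angle_pq=p.geometry.angle_pq,
                angle_xp=p.geometry.angle_xp,
                offset_xq=p.geometry.offset_xq, offset_pq=p.geometry.offset_pq,
            )
            if lab_iter is not None:
                row["label"] = next(lab_iter).label.value
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """One ensemble run: per-conformer table, summary, density, provenance."""

    per_conformer: pd.DataFrame
    summary: EnsembleSummary
    skipped_models: list[int]
    config: dict[str, Any]
    density_grid_path: str | None = None
    version: str = __version__

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "version": self.version,
            "config": self.config,
            "n_models": self.summary.n_total + len(self.skipped_models),
            "n_skipped": len(self.skipped_models),
            "skipped_models": self.skipped_models,
            "counts": self.summary.counts,
            "fractions": self.summary.fractions,
            "wilson_ci95": {k: list(v) for k, v in self.summary.intervals.items()},
            "density_grid": self.density_grid_path,
        }


def _load_models(models: Sequence[MolecularModel] | str | os.PathLike) -> list[MolecularModel]:
    if isinstance(models, (str, os.PathLike)):
        return read_models(models)
    return list(models)


def run_ensemble_analysis(
    models: Sequence[MolecularModel] | str | os.PathLike,
    moiety_config: Mapping[str, Any],
    config: RunConfig = RunConfig(),
    density_out: str | os.PathLike | None = None,
) -> AnalysisReport:
    """Profile, classify and summarize a conformer ensemble.

    Models whose quencher is unresolved are skipped and tallied, mirroring
    partially disordered quenchers in crystal models. When *density_out* is
    given, a quencher occupancy grid (fraction-of-max) is written there.
    """
    models = _load_models(models)
    profiles: list[ConformerProfile] = []
    mmap: MoietyMap | None = None
    for m in models:
        mmap_m = resolve_moieties(m, moiety_config, required=("xanthene", "phenyl"))
        if mmap is None or (not mmap.quencher and mmap_m.quencher):
            mmap = mmap_m
        profiles.append(profile_conformer(m, mmap_m, config.contact_cutoff))
    labels, skipped = labels_from_profiles(profiles, config.criteria, config.contact_cutoff_q)
    summary = EnsembleSummary(
        n_total=len(labels),
        counts={
            k: sum(1 for l in labels if l.label.value == k)
            for k in ("StackX", "StackP", "ContactUnstacked", "NonContact")
        },
        settings=config.echo(),
    )
    table = profiles_to_frame([p for p in profiles if p.complete], labels)

    grid_path = None
    if density_out is not None:
        grid = accumulate_density(
            [m for m, p in zip(models, profiles) if p.complete],
            mmap, spacing=config.grid_spacing,
        )
        write_grid(grid, density_out)
        grid_path = os.fspath(density_out)
    return AnalysisReport(table, summary, skipped, config.echo(), grid_path)


@dataclass
class ComparisonReport:
    deltas: list[ClassDelta]
    summary_a: EnsembleSummary
    summary_b: EnsembleSummary

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(d) for d in self.deltas])


def run_comparison(report_a: AnalysisReport, report_b: AnalysisReport) -> ComparisonReport:
    """Class-by-class comparison of two analysed ensembles (B minus A)."""
    deltas = compare_ensembles(report_a.summary, report_b.summary)
    return ComparisonReport(deltas, report_a.summary, report_b.summary)


def run_interface_table(
    entries: Sequence[Mapping[str, Any]],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
) -> pd.DataFrame:
    """Buried-interface table across complexes, one row per entry.

    Each entry needs ``name``, ``model`` (a MolecularModel or a PDB path) and
    a ``moiety_config``; optional ``moieties`` lists ligand moieties whose
    individual burial is reported. Per-entry failures land in an ``error``
    column and the run continues.
    """
    rows = []
    for entry in entries:
        row: dict[str, Any] = {"name": entry.get("name", "?")}
        try:
            model = entry["model"]
            if isinstance(model, (str, os.PathLike)):
                model = read_models(model)[0]
            mmap = resolve_moieties(model, entry["moiety_config"])
            res: InterfaceResult = buried_interface(
                model, receptor=mmap.rna, ligand=mmap.ligand, channel_ions=mmap.ions,
                probe_radius=probe_radius, n_sphere_points=n_sphere_points,
            )
            row.update(
                sasa_receptor=res.sasa_receptor, sasa_ligand=res.sasa_ligand,
                sasa_complex=res.sasa_complex, interface_area=res.interface_area,
                relative_interface_pct=100.0 * res.relative_interface,
            )
            for name in entry.get("moieties", ()):
                mb = moiety_burial(
                    model, receptor=mmap.rna, ligand=mmap.ligand,
                    moiety_atoms=mmap[name] if name != "fluorophore" else mmap.fluorophore,
                    moiety_name=name, channel_ions=mmap.ions,
                    probe_radius=probe_radius, n_sphere_points=n_sphere_points,
                )
                row[f"{name}_burial_pct"] = 100.0 * mb.fraction
                row[f"{name}_burial_of_ligand_pct"] = 100.0 * mb.fraction_of_ligand
        except Exception as exc:  # per-row isolation is the contract
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: AnalysisReport, out_dir: str | os.PathLike,
                 stem: str = "ensemble") -> dict[str, str]:
    """Write JSON summary + TSV per-conformer table; returns written paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    jpath = os.path.join(os.fspath(out_dir), f"{stem}_summary.json")
    with open(jpath, "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
    paths["summary"] = jpath
    tpath = os.path.join(os.fspath(out_dir), f"{stem}_per_conformer.tsv")
    report.per_conformer.to_csv(tpath, sep="\t", index=False)
    paths["per_conformer"] = tpath
    return paths
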