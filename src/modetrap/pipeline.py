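"""Workflow orchestration: the full displace–relax–design loop and the
ensemble-evaluation layer, as plain functions over the library modules.

``run_melt`` executes the design procedure on one input structure:

1. build an elastic network and diagonalize it;
2. displace the structure along the chosen mode in both directions;
3. relax each displaced conformer with the restrained minimizer;
4. design sequences on each relaxed conformer (several seeds per
   direction);
5. evaluate U(R_opt|M_wt), U(R_opt|M_eng), U(R_min|M_wt), U(R_min|M_eng)
   and classify each design as landscape trap / smoothing / neither.

Every stochastic stage's seed and every default in effect is serialized
into the returned manifest, so a rerun from the manifest reproduces the
outputs bit-for-bit.

``run_evaluation`` mirrors the analysis layer: collective-coordinate
distance series and density peaks, RMSF profiles and their correlation
matrix, projections onto the low modes, and rank-sum comparisons against a
designated reference system.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    ContactEnergyModel,
    DesignConfig,
    Sequence,
    classify_landscape,
    contact_energy,
    load_energy_matrix,
    mc_design,
    mutation_report,
)
from .displacement import DisplacementSpec, displace, solve_scaling_factor
from .dynamics import (
    TrajectoryEnsemble,
    density_peaks,
    distance_series,
    load_ensemble,
    mann_whitney_u,
    project_ensemble,
    rmsf,
    rmsf_correlation,
)
from .enm import ENMPreset, ModeSet, build_network, diagonalize
from .relaxation import GeometricEnergyParams, minimize_restrained
from .structure import Structure, read_pdb, rmsd, sequence_of, write_pdb


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of one design run; every field lands in the manifest."""

    structure_path: str | None = None          # PDB input (or pass a Structure)
    enm_preset: str = "inverse-power"
    enm_cutoff: float = 10.0
    mode: int = 7
    directions: tuple[int, ...] = (1, -1)       # +1 / −1 along the mode
    amplitude: float = 2.0                      # Å
    amplitude_convention: str = "rms-all-atom"
    relax_params: GeometricEnergyParams = field(default_factory=GeometricEnergyParams)
    design_seeds: tuple[int, ...] = (11, 17)    # designs per direction
    design_schedule: tuple[tuple[float, int], ...] = (
        (1.0, 2000), (0.3, 2000), (0.1, 2000)
    )
    designable_positions: tuple[int, ...] | None = None
    energy_matrix_path: str | None = None       # None = shipped matrix
    classification_tol: float = 0.5
    probe_pair: tuple[int, int] | None = None   # residue ids for open/closed labels
    output_dir: str | None = None

    def validate(self) -> None:
        if self.mode < 7:
            raise PipelineError("config", "mode must be a nontrivial index (>= 7)")
        if self.amplitude < 0:
            raise PipelineError("config", "amplitude must be >= 0")
        if not self.directions or any(d not in (-1, 1) for d in self.directions):
            raise PipelineError("config", "directions must be drawn from {+1, -1}")
        if not self.design_seeds:
            raise PipelineError("config", "at least one design seed required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        if "relax_params" in raw and isinstance(raw["relax_params"], dict):
            raw["relax_params"] = GeometricEnergyParams(**raw["relax_params"])
        for key in ("directions", "design_seeds", "designable_positions", "probe_pair"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "design_schedule" in raw:
            raw["design_schedule"] = tuple(
                (float(kt), int(n)) for kt, n in raw["design_schedule"]
            )
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["relax_params"] = asdict(self.relax_params)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _direction_label(
    s: Structure, displaced: Structure, probe_pair: tuple[int, int] | None, sign: int
) -> str:
    if probe_pair is None:
        return "plus" if sign > 0 else "minus"
    from .dynamics import _ca_atom_index

    ia = _ca_atom_index(s, probe_pair[0])
    ib = _ca_atom_index(s, probe_pair[1])
    d0 = float(np.linalg.norm(s.coords[ib] - s.coords[ia]))
    d1 = float(np.linalg.norm(displaced.coords[ib] - displaced.coords[ia]))
    return "open" if d1 > d0 else "closed"


def run_melt(
    cfg: RunConfig,
    structure: Structure | None = None,
    model: ContactEnergyModel | None = None,
) -> dict:
    """Execute the full design procedure; returns the manifest dictionary.

    Artifacts (displaced/relaxed PDBs, designed FASTAs, manifest JSON) are
    written when ``cfg.output_dir`` is set.  On a stage failure the partial
    manifest collected so far is attached to the raised
    :class:`PipelineError`.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": json.loads(json.dumps(
        {**asdict(cfg), "relax_params": asdict(cfg.relax_params)}, default=list
    ))}
    try:
        if structure is None:
            if cfg.structure_path is None:
                raise PipelineError("input", "no structure given")
            structure = read_pdb(cfg.structure_path)
    except FileNotFoundError as exc:
        raise PipelineError("input", str(exc)) from exc

    try:
        preset = ENMPreset.named(cfg.enm_preset, cutoff=cfg.enm_cutoff)
        net = build_network(structure, preset)
        ms = diagonalize(net)
        manifest["enm"] = {
            "preset": preset.describe(),
            "n_nodes": net.n_nodes,
            "n_springs": net.n_springs,
            "n_trivial": ms.n_trivial,
            "connected": net.connected,
        }
    except Exception as exc:
        raise PipelineError("modes", str(exc)) from exc

    if model is None:
        model = load_energy_matrix(cfg.energy_matrix_path)
    manifest["energy_matrix"] = model.name
    wt = sequence_of(structure)
    u_min_wt = contact_energy(structure, wt, model)
    manifest["wild_type"] = {"sequence": wt.letters, "u_min_wt": u_min_wt}

    branches = {}
    designs_for_report: dict[str, Sequence] = {}
    for sign in cfg.directions:
        spec = DisplacementSpec(
            mode_indices=(cfg.mode,),
            coefficients=(float(sign),),
            amplitude=cfg.amplitude,
            amplitude_convention=cfg.amplitude_convention,
        )
        try:
            displaced = displace(structure, ms, spec)
            lam = float(sign) * solve_scaling_factor(structure, ms, spec)
        except Exception as exc:
            raise PipelineError("displace", str(exc)) from exc
        label = _direction_label(structure, displaced, cfg.probe_pair, sign)
        try:
            relax = minimize_restrained(displaced, structure, cfg.relax_params)
        except Exception as exc:
            raise PipelineError("relax", str(exc)) from exc
        r_opt = relax.structure
        u_opt_wt = contact_energy(r_opt, wt, model)
        branch = {
            "sign": int(sign),
            "scaling_factor": lam,
            "rmsd_displaced_to_input": rmsd(displaced, structure),
            "rmsd_displaced_to_input_calpha": rmsd(displaced, structure, "name CA"),
            "relax": {
                "converged": relax.converged,
                "n_iterations": relax.n_iterations,
                "rmsd_to_anchor": relax.rmsd_to_anchor,
                "rmsd_to_original": relax.rmsd_to_original,
                "closer_to_anchor": relax.closer_to_anchor,
            },
            "u_opt_wt": u_opt_wt,
            "designs": {},
        }
        if outdir:
            write_pdb(displaced, outdir / f"displaced_{label}.pdb")
            write_pdb(r_opt, outdir / f"relaxed_{label}.pdb")
        for i, seed in enumerate(cfg.design_seeds, start=1):
            dcfg = DesignConfig(
                seed=seed,
                schedule=cfg.design_schedule,
                designable_positions=cfg.designable_positions,
            )
            try:
                dres = mc_design(r_opt, wt, model, dcfg)
            except Exception as exc:
                raise PipelineError("design", str(exc)) from exc
            m_eng = dres.best_sequence
            u_opt_eng = contact_energy(r_opt, m_eng, model)
            u_min_eng = contact_energy(structure, m_eng, model)
            verdict = classify_landscape(
                u_opt_wt, u_opt_eng, u_min_wt, u_min_eng, cfg.classification_tol
            )
            name = f"{label.upper()}{i}"
            branch["designs"][name] = {
                "seed": seed,
                "sequence": m_eng.letters,
                "n_mutations": len(dres.mutations),
                "mutations": [list(m) for m in dres.mutations],
                "u_opt_eng": u_opt_eng,
                "u_min_eng": u_min_eng,
                "u_opt_wt": u_opt_wt,
                "u_min_wt": u_min_wt,
                "trap_inequality": bool(u_opt_eng <= u_opt_wt),
                "classification": verdict,
            }
            designs_for_report[name] = m_eng
            if outdir:
                m_eng.to_fasta(outdir / f"design_{name}.fasta", header=name)
        branches[label] = branch
    manifest["branches"] = branches
    if len(designs_for_report) > 1:
        report = mutation_report(wt, designs_for_report)
        manifest["mutation_summary"] = {
            "n_positions_mutated": int(report["mutated"].sum()),
            "n_group_specific": int(report["group_specific"].sum()),
            "n_global_convergence": int(report["global_convergence"].sum()),
        }
        if outdir:
            report.to_csv(outdir / "mutation_report.csv", index=False)
    if outdir:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_evaluation(
    ensembles: Mapping[str, TrajectoryEnsemble] | Mapping[str, TypingSequence[str]],
    probe_pair: tuple[int, int],
    modeset: ModeSet | None = None,
    reference_structure: Structure | None = None,
    reference_label: str | None = None,
    modes: tuple[int, ...] = (7, 8),
    topology: Structure | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Analyze named conformational ensembles and compare them.

    ``ensembles`` maps system labels to loaded ensembles (or lists of
    multi-model PDB paths).  Produces per-system distance series and
    density peaks, RMSF profiles, the RMSF correlation matrix, optional
    mode projections, and two-sided rank-sum tests of every system's
    distance distribution against the reference system's.
    """
    loaded: dict[str, TrajectoryEnsemble] = {}
    for label, item in ensembles.items():
        if isinstance(item, TrajectoryEnsemble):
            loaded[label] = item
        else:
            loaded[label] = load_ensemble(item, topology=topology)
    if not loaded:
        raise PipelineError("evaluation", "no ensembles given")
    if reference_label is None:
        reference_label = next(iter(loaded))
    if reference_label not in loaded:
        raise PipelineError("evaluation", f"unknown reference {reference_label!r}")

    outdir = Path(output_dir) if output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    result: dict = {"reference": reference_label, "systems": {}}
    series: dict[str, np.ndarray] = {}
    profiles: dict[str, np.ndarray] = {}
    for label, ens in loaded.items():
        ds = distance_series(ens, probe_pair[0], probe_pair[1])
        series[label] = ds.values
        peaks = density_peaks(ds)
        ids, prof = rmsf(ens)
        profiles[label] = prof
        entry = {
            "n_frames": ens.n_frames,
            "replica_boundaries": list(ens.replica_boundaries),
            "distance_median": float(np.median(ds.values)),
            "distance_mean": float(np.mean(ds.values)),
            "distance_std": float(np.std(ds.values)),
            "density_peaks": list(peaks.peaks),
            "kde_bandwidth": peaks.bandwidth,
        }
        if modeset is not None and reference_structure is not None:
            proj = project_ensemble(ens, modeset, reference_structure, modes=modes)
            entry["projection_means"] = [float(v) for v in proj.mean(axis=0)]
            entry["projection_stds"] = [float(v) for v in proj.std(axis=0)]
            if outdir:
                pd.DataFrame(
                    proj, columns=[f"mode_{k}" for k in modes]
                ).to_csv(outdir / f"projections_{label}.csv", index=False)
        result["systems"][label] = entry
        if outdir:
            pd.DataFrame(
                {"frame": np.arange(len(ds.values)), "distance": ds.values}
            ).to_csv(outdir / f"distance_{label}.csv", index=False)
            pd.DataFrame({"residue_id": ids, "rmsf": prof}).to_csv(
                outdir / f"rmsf_{label}.csv", index=False
            )

    labels = list(loaded)
    corr = pd.DataFrame(
        [
            [
                1.0 if a == b else rmsf_correlation(profiles[a], profiles[b])
                for b in labels
            ]
            for a in labels
        ],
        index=labels,
        columns=labels,
    )
    result["rmsf_correlation"] = corr.to_dict()
    ref_vals = series[reference_label]
    comparisons = {}
    for label in labels:
        if label == reference_label:
            continue
        mw = mann_whitney_u(series[label], ref_vals)
        comparisons[label] = {
            "U": mw.u_statistic,
            "p_value": mw.p_value,
            "method": mw.method,
            "median_shift": float(
                np.median(series[label]) - np.median(ref_vals)
            ),
        }
    result["rank_sum_vs_reference"] = comparisons
    if outdir:
        corr.to_csv(outdir / "rmsf_correlation.csv")
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
    return result


# ---------------------------------------------------------------------------
# Desk-scale directional-shift experiment
# ---------------------------------------------------------------------------

@dataclass
class DirectionalShiftResult:
    system_seed: int
    wt_median: float
    closed_median_shift: float
    open_median_shift: float
    closed_p: float
    open_p: float

    @property
    def closed_ok(self) -> bool:
        return self.closed_median_shift < 0 and self.closed_p < 1e-3

    @property
    def open_ok(self) -> bool:
        return self.open_median_shift > 0 and self.open_p < 1e-3


def directional_shift_experiment(
    system_seeds: TypingSequence[int] = (1, 2, 3, 4, 5),
    sampler_seed: int = 100,
    design_amplitude: float = 3.0,
    n_steps: int = 30_000,
) -> list[DirectionalShiftResult]:
    """Design-then-sample on a family of jittered two-domain systems.

    For each seeded system the cleft-face positions are redesigned against
    the closed- and open-displaced (relaxed) conformers, and the wild-type
    and designed sequences are each sampled on the same mode-space
    landscape.  Reported per system: the shift of the median probe
    distance and the rank-sum p-value of each design against wild type.
    The expected physics: closed designs shift the distribution down,
    open designs up.
    """
    from .toys import SamplerConfig, make_two_domain, sample_landscape, toy_contact_model

    model = toy_contact_model()
    results = []
    for k, sysseed in enumerate(system_seeds):
        sys_ = make_two_domain(12, 8, jitter=0.35, seed=sysseed)
        s = sys_.structure
        ms = diagonalize(build_network(s, ENMPreset()))
        wt = sequence_of(s)
        ia, ib = sys_.probe_pair
        iao, ibo = ia - 1, ib - 1
        d_ref = float(np.linalg.norm(s.coords[ibo] - s.coords[iao]))
        designed = {}
        for sign in (-1, 1):
            spec = DisplacementSpec(
                mode_indices=(7,), coefficients=(float(sign),),
                amplitude=design_amplitude,
            )
            displaced = displace(s, ms, spec)
            d_disp = float(
                np.linalg.norm(displaced.coords[ibo] - displaced.coords[iao])
            )
            relaxed = minimize_restrained(displaced, s).structure
            dres = mc_design(
                relaxed, wt, model,
                DesignConfig(
                    seed=11,
                    schedule=((0.02, 1000), (0.005, 1000)),
                    designable_positions=(ia, ib),
                ),
            )
            # label by what the displacement did, not by the sign convention
            designed["closed" if d_disp < d_ref else "open"] = dres.best_sequence
        if set(designed) != {"closed", "open"}:
            raise PipelineError(
                "design", f"system {sysseed}: both directions moved the probe one way"
            )
        cfg = SamplerConfig(seed=sampler_seed + k, n_steps=n_steps)
        dist = {}
        for key, seq in (("wt", wt), ("closed", designed["closed"]), ("open", designed["open"])):
            ens = sample_landscape(sys_, ms, seq, model, cfg)
            dist[key] = distance_series(ens, ia, ib).values
        wt_med = float(np.median(dist["wt"]))
        results.append(
            DirectionalShiftResult(
                system_seed=sysseed,
                wt_median=wt_med,
                closed_median_shift=float(np.median(dist["closed"]) - wt_med),
                open_median_shift=float(np.median(dist["open"]) - wt_med),
                closed_p=mann_whitney_u(dist["closed"], dist["wt"]).p_value,
                open_p=mann_whitney_u(dist["open"], dist["wt"]).p_value,
            )
        )
    return results
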