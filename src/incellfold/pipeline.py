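"""Stage orchestration: reconstruct -> pick -> assign -> calibrate ->
anneal -> refine -> analyze.

Every stage reads its inputs from disk, writes its outputs plus a manifest
into the run directory, and can be run standalone; ``run_pipeline`` chains
the enabled stages and saves a resolved copy of the configuration (all
defaults materialized) so a run can be reproduced exactly.  Seeds are
explicit in the configuration; two runs with the same resolved config give
byte-identical numeric outputs on one machine.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import anneal as anneal_mod
from . import cybay, ensemble_analysis, formats_io, noe_restraints, nus_maxent
from .formats_io import RestraintRecord
from .molecule import TorsionConformer, build_coordinates, measure_torsions, \
    CartesianStructure

log = logging.getLogger("incellfold")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; serializable to a single YAML file."""

    outdir: str = "run"
    seed: int = 0
    sequence: str = ""

    # stage toggles
    reconstruct: bool = True
    pick: bool = True
    assign: bool = True
    do_calibrate: bool = True
    do_anneal: bool = True
    refine: bool = True
    analyze: bool = True

    # inputs
    fid_path: str = ""
    peak_paths: list = field(default_factory=list)
    shift_path: str = ""
    aco_path: str = ""

    # reconstruction
    lam: str | float = "auto"
    peak_threshold: float = 5.0

    # assignment / calibration
    tol_h: float = noe_restraints.TOL_H_DEFAULT
    tol_heavy: float = noe_restraints.TOL_HEAVY_DEFAULT
    min_support: int = 0
    cal_target_median: float = noe_restraints.CAL_TARGET_MEDIAN
    cal_d_min: float = noe_restraints.CAL_D_MIN
    cal_d_max: float = noe_restraints.CAL_D_MAX

    # annealing
    n_starts: int = 100
    n_steps: int = 10000

    # refinement (production-scale replica count; step counts desk-scale)
    n_replicas: int = 10
    t_min: float = 300.0
    t_max: float = 400.0
    total_steps: int = 200_000
    exchange_interval: int = 100
    burn_in: int = 40_000
    stride: int = 5000

    # analysis
    subsample_fraction: float = 0.2

    def validate(self):
        if self.tol_h <= 0 or self.tol_heavy <= 0:
            raise ValueError("matching tolerances must be > 0")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.stride % self.exchange_interval:
            raise ValueError("stride must be a multiple of exchange_interval")
        if isinstance(self.lam, str) and self.lam != "auto":
            raise ValueError("lam must be 'auto' or a positive number")
        if not isinstance(self.lam, str) and self.lam <= 0:
            raise ValueError("lam must be 'auto' or a positive number")
        enabled_need_seq = (self.do_anneal or self.refine or self.analyze
                            or self.assign)
        if enabled_need_seq and not self.sequence:
            raise ValueError("sequence is required for the enabled stages")
        return self

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _write_restraints_json(restraints, path):
    rows = []
    for r in restraints:
        rows.append({
            "options": [[list(a), list(b)] for (a, b) in r.options],
            "upper": r.upper_bound, "lower": r.lower_bound,
            "spectrum_id": r.spectrum_id, "peak_id": r.peak_id,
            "intensity": None if r.intensity != r.intensity else r.intensity,
        })
    Path(path).write_text(json.dumps(rows, indent=1))


def _read_restraints_json(path):
    rows = json.loads(Path(path).read_text())
    out = []
    for row in rows:
        out.append(RestraintRecord(
            options=tuple(((int(a[0]), a[1]), (int(b[0]), b[1]))
                          for a, b in row["options"]),
            upper_bound=row["upper"], lower_bound=row["lower"],
            spectrum_id=row["spectrum_id"], peak_id=row["peak_id"],
            intensity=(float("nan") if row["intensity"] is None
                       else row["intensity"]),
        ))
    return out


def _manifest(outdir: Path, stage: str, outputs: dict):
    (outdir / f"{stage}.manifest.json").write_text(
        json.dumps({"stage": stage, "outputs": outputs}, indent=1))


def _require(path, stage: str):
    if not path or not Path(path).exists():
        raise FileNotFoundError(
            f"stage '{stage}': required input {path!r} does not exist")
    return Path(path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the enabled stages; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_yaml(outdir / "resolved_config.yaml")
        peak_paths = list(config.peak_paths)

        if config.reconstruct:
            fid = formats_io.read_fid(_require(config.fid_path, "reconstruct"))
            if config.lam == "auto":
                lam, _trace = nus_maxent.select_lambda(fid)
            else:
                lam = float(config.lam)
            sol = nus_maxent.reconstruct(fid, lam)
            formats_io.write_spectrum(sol.spectrum, outdir / "spectrum.txt")
            log.info("reconstruct: lambda=%g iterations=%d", lam,
                     sol.iterations)
            _manifest(outdir, "reconstruct",
                      {"spectrum": "spectrum.txt", "lambda": lam})

        if config.pick:
            spec = formats_io.read_spectrum(
                _require(outdir / "spectrum.txt", "pick"))
            fid = formats_io.read_fid(_require(config.fid_path, "pick"))
            noise = (fid.noise_sigma if fid.noise_sigma
                     else nus_maxent.estimate_noise(fid))
            peaks = nus_maxent.pick_peaks(spec, config.peak_threshold, noise)
            formats_io.write_peak_list(peaks, outdir / "picked_peaks.list")
            log.info("pick: %d peaks above %gx noise", len(peaks),
                     config.peak_threshold)
            _manifest(outdir, "pick", {"peaks": "picked_peaks.list",
                                       "count": len(peaks)})

        restraints = None
        if config.assign or config.do_calibrate:
            shifts = formats_io.read_shift_list(
                _require(config.shift_path, "assign"))
            all_restraints = []
            for p in peak_paths:
                peaks = formats_io.read_peak_list(_require(p, "assign"))
                cands = noe_restraints.match_assignments(
                    peaks, shifts, config.tol_h, config.tol_heavy)
                cands = noe_restraints.network_filter(cands,
                                                      config.min_support)
                pos = [c.peak.intensity for c in cands
                       if not c.unassigned and c.peak.intensity > 0]
                model = noe_restraints.CalibrationModel(
                    spectrum_id=peaks[0].spectrum_id if peaks else "spec",
                    constant=noe_restraints.auto_calibration_constant(
                        pos, config.cal_target_median),
                    d_min=config.cal_d_min, d_max=config.cal_d_max)
                rset = noe_restraints.calibrate(cands, model)
                all_restraints.extend(rset.restraints)
                log.info("assign/calibrate %s: %d peaks -> %d restraints "
                         "(C=%g)", p, len(peaks), len(rset), model.constant)
            restraints = all_restraints
            formats_io.write_upl(restraints, outdir / "restraints.upl")
            _write_restraints_json(restraints, outdir / "restraints.json")
            counts = noe_restraints.RestraintSet(restraints).count_by_class()
            _manifest(outdir, "calibrate",
                      {"upl": "restraints.upl",
                       "restraints_json": "restraints.json",
                       "counts": counts})

        dihedrals = (formats_io.read_aco(config.aco_path)
                     if config.aco_path else [])

        seed_conf = None
        if config.do_anneal:
            if restraints is None:
                restraints = _read_restraints_json(
                    _require(outdir / "restraints.json", "anneal"))
            acfg = anneal_mod.AnnealConfig(n_starts=config.n_starts,
                                           n_steps=config.n_steps,
                                           seed=config.seed)
            results = anneal_mod.run_annealing(config.sequence, restraints,
                                               acfg, dihedrals)
            seed_conf = anneal_mod.select_seed(results)
            with open(outdir / "anneal_targets.tsv", "w") as fh:
                fh.write("rank\ttarget\n")
                for k, (_c, t) in enumerate(results):
                    fh.write(f"{k}\t{t:.6g}\n")
            formats_io.write_pdb_models(
                [build_coordinates(c).atoms for c, _t in results[:20]],
                outdir / "annealed.pdb")
            formats_io.write_pdb_models(
                [build_coordinates(seed_conf).atoms], outdir / "seed.pdb")
            log.info("anneal: best target %g", results[0][1])
            _manifest(outdir, "anneal", {"seed": "seed.pdb",
                                         "targets": "anneal_targets.tsv",
                                         "best_target": results[0][1]})

        ens_states = None
        if config.refine:
            if restraints is None:
                restraints = _read_restraints_json(
                    _require(outdir / "restraints.json", "refine"))
            if seed_conf is None:
                models = formats_io.read_pdb_models(
                    _require(outdir / "seed.pdb", "refine"))
                seed_conf = measure_torsions(
                    CartesianStructure.from_atom_records(models[0]))
            rcfg = cybay.RexmcConfig(
                n_replicas=config.n_replicas, t_min=config.t_min,
                t_max=config.t_max, total_steps=config.total_steps,
                exchange_interval=config.exchange_interval,
                seed=config.seed)
            trace = cybay.run_rexmc(seed_conf, restraints, rcfg)
            ens_states = cybay.burn_and_thin(trace, config.burn_in,
                                             config.stride)
            with open(outdir / "trace.tsv", "w") as fh:
                ids = ens_states[0].nuisance.spectrum_ids if ens_states else []
                cols = "\t".join(
                    [f"logpost_r{k}" for k in
                     range(trace.log_posteriors.shape[1])])
                fh.write(f"step\t{cols}\n")
                for step, row in zip(trace.steps, trace.log_posteriors):
                    vals = "\t".join(f"{v:.6g}" for v in row)
                    fh.write(f"{step}\t{vals}\n")
            formats_io.write_pdb_models(
                [build_coordinates(st.conformer).atoms for st in ens_states],
                outdir / "ensemble.pdb")
            mp = cybay.map_state(ens_states)
            formats_io.write_pdb_models(
                [build_coordinates(mp.conformer).atoms], outdir / "map.pdb")
            log.info("refine: %d ensemble members, exchange rates %s",
                     len(ens_states), trace.exchange_rates())
            _manifest(outdir, "refine",
                      {"ensemble": "ensemble.pdb", "map": "map.pdb",
                       "trace": "trace.tsv",
                       "n_members": len(ens_states)})

        if config.analyze:
            if ens_states is not None:
                ens = ensemble_analysis.Ensemble.from_posterior_states(
                    ens_states)
            else:
                models = formats_io.read_pdb_models(
                    _require(outdir / "ensemble.pdb", "analyze"))
                structs = [CartesianStructure.from_atom_records(m)
                           for m in models]
                ens = ensemble_analysis.Ensemble(
                    structs, np.zeros(len(structs)))
            mean = ensemble_analysis.mean_structure(ens)
            ref = CartesianStructure(ens.template.sequence, mean)
            rb, sb = ensemble_analysis.per_residue_rmsd(ens, ref, "backbone")
            rs, ss = ensemble_analysis.per_residue_rmsd(ens, ref, "sidechain")
            with open(outdir / "per_residue_rmsd.tsv", "w") as fh:
                fh.write("residue\tbackbone\tbackbone_sd\tsidechain"
                         "\tsidechain_sd\n")
                for r in range(len(rb)):
                    fh.write(f"{r+1}\t{rb[r]:.4f}\t{sb[r]:.4f}\t{rs[r]:.4f}"
                             f"\t{ss[r]:.4f}\n")
            pca = ensemble_analysis.pca_ensemble(ens)
            with open(outdir / "pca_projections.tsv", "w") as fh:
                fh.write("member\t" + "\t".join(
                    f"PC{k+1}" for k in range(pca.projections.shape[1]))
                    + "\n")
                for m, row in enumerate(pca.projections):
                    fh.write(f"{m}\t" + "\t".join(f"{v:.5g}" for v in row)
                             + "\n")
            sub = ensemble_analysis.subsample(ens, config.subsample_fraction,
                                              config.seed)
            formats_io.write_pdb_models(
                [s.atoms for s in sub.structures],
                outdir / "ensemble_subsampled.pdb")
            log.info("analyze: mean backbone rmsd %.3f A",
                     ensemble_analysis.rmsd_to_mean(ens))
            _manifest(outdir, "analyze",
                      {"per_residue_rmsd": "per_residue_rmsd.tsv",
                       "pca": "pca_projections.tsv",
                       "subsampled": "ensemble_subsampled.pdb",
                       "n_subsampled": len(sub)})
        return outdir
    finally:
        log.removeHandler(handler)
        handler.close()
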