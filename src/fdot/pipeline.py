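"""End-to-end study driver on the synthetic phantom population.

Reproduces the study design at desk scale: generate a reference phantom
and a varying population, place the probe on the reference, split the
CSF, register every subject into the reference exterior shell (with
QC), simulate FD measurements and absorption sensitivities for every
accepted anatomy, and compute the approximation-error statistics and
detectability ratios in absolute and difference mode.

The default solver is the deterministic diffusion approximation (a
rerun with the same config is bit-identical); the Monte Carlo path uses
the same schemas and is selected with ``solver="mc"``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import mc as mc_mod
from . import mc_jacobian as mcj
from .approx_error import (ErrorStatistics, absolute_error_stats,
                           difference_error_stats, difference_ratios,
                           eigenvalue_fraction_count, projection_ratio_mean,
                           signal_visibility)
from .csf import split_csf
from .da import DASolver, assemble_measurement_vector_da, voxel_to_mesh
from .geometry import VoxelHeadModel
from .measurement import MeasurementVector
from .optical import OpticalTable, Tissue, default_table
from .phantom import (HeadParams, PopulationSpread, cranial_points,
                      generate_head, generate_population, place_probe,
                      probe_template_grid)
from .registration import (affine_fit, fill_reference_shell,
                           probe_region_scaling, resample_to_reference)

__all__ = ["StudyConfig", "StudyResult", "run_study"]


@dataclass
class StudyConfig:
    """Fully serializable study configuration; a run is reproducible
    from the config alone."""

    N: int = 20
    seed: int = 1234
    solver: str = "da"              # "da" or "mc"
    f: float = 0.1                  # modulation frequency [GHz]
    sds_max: float = 55.0           # SDS mask [mm]
    n_photons: int = 200_000        # per source (MC)
    # phantom geometry and population spread
    head: HeadParams = field(default_factory=HeadParams)
    spread: PopulationSpread = field(default_factory=PopulationSpread)
    # probe
    probe_n_side: int = 2
    probe_pitch: float = 12.0
    probe_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    # CSF split
    csf_split: bool = True
    csf_theta: float = 0.6
    csf_buffer: float = 1.0
    # registration
    gamma1: float = 0.45
    gamma2: float = 0.55
    shell_thickness: float = 2.0
    probe_region_radius: float = 60.0
    # solver discretization
    sim_spacing: float = 1.0        # voxel models for MC [mm]
    mesh_spacing: float = 2.5       # DA tet mesh from downsampled labels [mm]
    # perturbations
    ball_radius: float = 5.0
    ball_delta_mu_a: float = 0.005  # mm^-1
    tissue_changes: tuple = ((Tissue.GM, -0.60), (Tissue.SCALP_SKULL, +0.60))
    output_dir: str | None = None

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissue_changes"] = [[int(t), float(c)] for t, c in self.tissue_changes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "head" in d and isinstance(d["head"], dict):
            d["head"] = HeadParams(**{**d["head"],
                                      "semi_axes": tuple(d["head"]["semi_axes"])})
        if "spread" in d and isinstance(d["spread"], dict):
            d["spread"] = PopulationSpread(**d["spread"])
        if "tissue_changes" in d:
            d["tissue_changes"] = tuple((Tissue(t), c) for t, c in d["tissue_changes"])
        if "probe_direction" in d:
            d["probe_direction"] = tuple(d["probe_direction"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    """Statistics and diagnostics of one study run."""

    config: StudyConfig
    n_accepted: int
    n_rejected: int
    abs_stats: dict                 # kind -> ErrorStatistics
    diff_stats: dict                # kind -> ErrorStatistics
    mu_ratio: dict                  # kind -> ||P_v mu_e|| / STD_e
    tissue_visibility: dict         # (tissue name, change) -> kind -> ratio
    ball_abs_visibility: dict       # kind -> ratio (absolute mode)
    ball_diff_ratios: dict          # kind -> (||dy||/||mu||, ||P_w dy||/STD)
    eig95: dict                     # kind -> #eigenvalues for 95% of trace
    registration_rmse: dict         # before/after means over subjects [mm]
    timings: dict = field(default_factory=dict)

    def summary_frame(self):
        import pandas as pd

        rows = []
        for kind in ("log_amplitude", "phase"):
            row = {"quantity": kind,
                   "mu_ratio": self.mu_ratio[kind],
                   "STD_abs": self.abs_stats[kind].STD,
                   "STD_diff": self.diff_stats[kind].STD,
                   "ball_abs_visibility": self.ball_abs_visibility[kind],
                   "ball_diff_mu_ratio": self.ball_diff_ratios[kind][0],
                   "ball_diff_visibility": self.ball_diff_ratios[kind][1],
                   "eig95_abs": self.eig95[kind]}
            for key, per_kind in self.tissue_visibility.items():
                row[f"visibility_{key}"] = per_kind[kind]
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _ball_center(head: VoxelHeadModel, probe_centroid: np.ndarray,
                 target: np.ndarray, extra_depth: float = 2.5) -> np.ndarray:
    """Centre of the activation ball: first GM along the inward ray from
    the probe centroid, pushed ``extra_depth`` mm deeper."""
    d = target - probe_centroid
    d = d / np.linalg.norm(d)
    step = head.spacing / 2.0
    for r in np.arange(0.0, 60.0, step):
        p = probe_centroid + r * d
        ijk = np.round(head.world_to_index(p)).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.array(head.shape)):
            continue
        if head.labels[tuple(ijk)] == int(Tissue.GM):
            return p + extra_depth * d
    raise RuntimeError("no grey matter under the probe")


def _ball_indicator(points: np.ndarray, center: np.ndarray, radius: float
                    ) -> np.ndarray:
    return (np.linalg.norm(points - center, axis=1) <= radius).astype(float)


def _da_measure_and_directional(head: VoxelHeadModel, layout, optics, cfg,
                                ball_center, solver_cache: dict):
    """DA forward measurements plus the directional derivative of every
    masked pair under the ball perturbation (per-anatomy row of
    (J dx))."""
    model = solver_cache.get("model")
    if model is None:
        model = voxel_to_mesh(head, layout, mesh_spacing=cfg.mesh_spacing)
        solver_cache["model"] = model
    else:
        # identical exterior => identical mesh geometry; only labels change
        hh = head.downsample_majority(int(round(cfg.mesh_spacing / head.spacing)))
        ii = np.floor((model.mesh.nodes[model.mesh.tets].mean(axis=1)
                       - hh.origin) / hh.spacing).astype(int)
        model = dataclasses.replace(
            model, mesh=dataclasses.replace(
                model.mesh, labels=hh.labels[ii[:, 0], ii[:, 1], ii[:, 2]].astype(int)))
    s = DASolver(model, optics, f=cfg.f)
    cents = model.mesh.nodes[model.mesh.tets].mean(axis=1)
    zeta = _ball_indicator(cents, ball_center, cfg.ball_radius) * cfg.ball_delta_mu_a
    n_s, n_d = layout.n_s, layout.n_d
    fwd = [s.solve_source(k) for k in range(n_s)]
    adj = [s.solve_adjoint(j) for j in range(n_d)]
    X = np.zeros(n_s * n_d)
    Y = np.zeros(n_s * n_d)
    for k in range(n_s):
        for j in range(n_d):
            M = s.boundary_measurement(fwd[k], j)
            X[k * n_d + j] = M.real
            Y[k * n_d + j] = -M.imag
    vec = MeasurementVector(X, Y, layout.sds_matrix().ravel(), n_s, n_d,
                            f=cfg.f, sds_max=cfg.sds_max)
    rows = {"log_amplitude": [], "phase": []}
    for k in range(n_s):
        for j in range(n_d):
            if not vec.mask[k * n_d + j]:
                continue
            M = s.boundary_measurement(fwd[k], j)
            dM = s.frechet_absorption(fwd[k], adj[j], zeta)
            d_lnA, d_phi = mcj.logamp_phase_jacobian(
                M.real, -M.imag, dM.real, -dM.imag)
            rows["log_amplitude"].append(d_lnA)
            rows["phase"].append(d_phi)
    jdx = {k: np.array(v) for k, v in rows.items()}
    return vec, jdx, s, model


def _mc_measure_and_directional(head: VoxelHeadModel, layout, optics, cfg,
                                ball_center, seed):
    vec, records = mc_mod.assemble_measurement_vector(
        head, optics, layout, cfg.n_photons, seed=seed, f=cfg.f,
        sds_max=cfg.sds_max, return_records=True)
    idx = np.indices(head.shape).reshape(3, -1).T
    centers = head.index_to_world(idx)
    zeta = _ball_indicator(centers, ball_center, cfg.ball_radius) * cfg.ball_delta_mu_a
    mu_a = mc_mod.mu_a_volume(head, optics)
    n_d = layout.n_d
    rows = {"log_amplitude": [], "phase": []}
    for rec in records:
        derivs = mcj.directional_derivative(rec, mu_a, cfg.f, zeta, n_d)
        for j, (dl, dp) in enumerate(derivs):
            if not vec.mask[rec.source_id * n_d + j]:
                continue
            rows["log_amplitude"].append(dl)
            rows["phase"].append(dp)
    jdx = {k: np.array(v) for k, v in rows.items()}
    return vec, jdx, records


# ---------------------------------------------------------------------------
# main driver
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig | None = None, verbose: bool = False
              ) -> StudyResult:
    cfg = config or StudyConfig()
    t_start = time.time()
    timings = {}

    def log(msg):
        if verbose:
            print(f"[{time.time() - t_start:7.1f}s] {msg}", flush=True)

    # 1. reference phantom, probe, CSF split -----------------------------
    t0 = time.time()
    ref = generate_head(cfg.seed, cfg.head)
    ref_points = cranial_points(ref)
    template = probe_template_grid(cfg.probe_n_side, cfg.probe_pitch)
    layout = place_probe(ref, template, direction=cfg.probe_direction)
    if cfg.csf_split:
        ref = split_csf(ref, theta=cfg.csf_theta, a=cfg.csf_buffer)
    probe_centroid = np.vstack([layout.source_positions,
                                layout.detector_positions]).mean(axis=0)
    ball_center = _ball_center(ref, probe_centroid, layout.launch_target)
    timings["reference"] = time.time() - t0
    log(f"reference ready; ball at {np.round(ball_center, 1)}")

    # 2. population ------------------------------------------------------
    t0 = time.time()
    population = generate_population(cfg.N, cfg.seed + 1, cfg.head, cfg.spread,
                                     with_points=True)
    timings["population"] = time.time() - t0
    log(f"{cfg.N} phantoms generated")

    # 3. registration into the reference shell ---------------------------
    t0 = time.time()
    probe_region = None
    idx = np.indices(ref.shape).reshape(3, -1).T
    vox_world = ref.index_to_world(idx)
    probe_region = (np.linalg.norm(vox_world - probe_centroid, axis=1)
                    < cfg.probe_region_radius).reshape(ref.shape)
    ref_surface = ref.surface_points()
    accepted, reports = [], []
    rmse_before, rmse_after = [], []
    for head, pts in population:
        if cfg.csf_split:
            head = split_csf(head, theta=cfg.csf_theta, a=cfg.csf_buffer)
        T, rep = affine_fit(pts, ref_points, cfg.gamma1, cfg.gamma2)
        subj_surface = T.apply(head.surface_points())
        S, _, _ = probe_region_scaling(subj_surface, ref_surface,
                                       probe_centroid,
                                       ref_points.landmarks["Nz"],
                                       radius=cfg.probe_region_radius)
        full = S.compose(T)
        warped = resample_to_reference(head, full, ref)
        filled, fill_rep = fill_reference_shell(
            ref, warped, cfg.shell_thickness, probe_region)
        rep.qc_rule1_pass = fill_rep.qc_rule1_pass
        rep.qc_rule2_pass = fill_rep.qc_rule2_pass
        rep.accepted = fill_rep.accepted
        reports.append(rep)
        rmse_before.append(rep.rmse_before)
        rmse_after.append(rep.rmse_after)
        if fill_rep.accepted:
            accepted.append(filled)
    timings["registration"] = time.time() - t0
    log(f"registration done: {len(accepted)} accepted / {cfg.N - len(accepted)} rejected")
    if len(accepted) < 2:
        raise RuntimeError("fewer than two subjects passed registration QC")

    # 4. forward solves + directional sensitivities ----------------------
    t0 = time.time()
    kinds = ("log_amplitude", "phase")
    optics = default_table(cfg.solver)
    if cfg.solver == "da":
        cache = {}
        ref_vec, ref_jdx, ref_solver, ref_model = _da_measure_and_directional(
            ref, layout, optics, cfg, ball_center, cache)
        pop_vecs, pop_jdx = [], []
        for i, h in enumerate(accepted):
            v, jd, _, _ = _da_measure_and_directional(
                h, layout, optics, cfg, ball_center, cache)
            v.mask = ref_vec.mask  # shared mask by construction
            pop_vecs.append(v)
            pop_jdx.append(jd)
            log(f"DA subject {i + 1}/{len(accepted)}")
    elif cfg.solver == "mc":
        ref_vec, ref_jdx, _ = _mc_measure_and_directional(
            ref, layout, optics, cfg, ball_center, cfg.seed + 101)
        pop_vecs, pop_jdx = [], []
        for i, h in enumerate(accepted):
            v, jd, _ = _mc_measure_and_directional(
                h, layout, optics, cfg, ball_center, cfg.seed + 211 + i)
            v.mask = ref_vec.mask & v.mask
            pop_vecs.append(v)
            pop_jdx.append(jd)
            log(f"MC subject {i + 1}/{len(accepted)}")
        # harmonize masks
        mask = ref_vec.mask.copy()
        for v in pop_vecs:
            mask &= v.mask
        ref_vec.mask = mask
        for v in pop_vecs:
            v.mask = mask
    else:
        raise ValueError(f"unknown solver {cfg.solver!r}")
    timings["forward"] = time.time() - t0

    # 5. statistics -------------------------------------------------------
    t0 = time.time()
    abs_stats, mu_ratio = {}, {}
    for kind in kinds:
        st = absolute_error_stats(ref_vec, pop_vecs, kind)
        abs_stats[kind] = st
        mu_ratio[kind] = projection_ratio_mean(st) if st.STD > 0 else 0.0

    # tissue-wide perturbations of the reference
    tissue_visibility = {}
    for tissue, change in cfg.tissue_changes:
        pert = _perturbed_table(optics, tissue, change)
        if cfg.solver == "da":
            pvec = assemble_measurement_vector_da(ref_model, pert, f=cfg.f,
                                                  sds_max=cfg.sds_max)
            pvec.mask = ref_vec.mask
        else:
            # mBLL: reweight stored trajectories under the new absorption
            pvec = _mc_reweighted_vector(ref, layout, optics, pert, cfg)
            pvec.mask = ref_vec.mask
        key = f"{tissue.name}_{change:+.0%}".replace("%", "pct")
        tissue_visibility[key] = {
            kind: signal_visibility(pvec.y(kind) - ref_vec.y(kind),
                                    abs_stats[kind])[0]
            for kind in kinds}

    # ball perturbation: absolute-mode visibility (reference difference
    # signal = J_ref dx to first order) and difference-mode statistics
    ball_abs_visibility = {}
    diff_stats, ball_diff_ratios, eig95 = {}, {}, {}
    for kind in kinds:
        dy_ref = ref_jdx[kind]
        ball_abs_visibility[kind] = signal_visibility(dy_ref, abs_stats[kind])[0]
        e_rows = np.array([ref_jdx[kind] - jd[kind] for jd in pop_jdx])
        st = difference_error_stats(e_rows, quantity=f"difference:{kind}")
        diff_stats[kind] = st
        ball_diff_ratios[kind] = difference_ratios(dy_ref, st)
        eig95[kind] = eigenvalue_fraction_count(abs_stats[kind])
    timings["statistics"] = time.time() - t0
    log("statistics done")

    result = StudyResult(
        config=cfg,
        n_accepted=len(accepted),
        n_rejected=cfg.N - len(accepted),
        abs_stats=abs_stats,
        diff_stats=diff_stats,
        mu_ratio=mu_ratio,
        tissue_visibility=tissue_visibility,
        ball_abs_visibility=ball_abs_visibility,
        ball_diff_ratios=ball_diff_ratios,
        eig95=eig95,
        registration_rmse={"before_mean": float(np.mean(rmse_before)),
                           "after_mean": float(np.mean(rmse_after))},
        timings=timings,
    )

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")
        result.summary_frame().to_csv(out / "summary.csv", index=False)
        ref_vec.to_csv(out / "reference_measurements.csv")
        manifest = {"config_digest": cfg.digest(),
                    "n_accepted": result.n_accepted,
                    "timings": timings}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _perturbed_table(optics: OpticalTable, tissue: Tissue, change: float
                     ) -> OpticalTable:
    from .optical import TissueOpticalProperties

    entries = {}
    for t in optics.tissues:
        p = optics[t]
        if t == tissue:
            p = TissueOpticalProperties(t, p.mu_a * (1.0 + change), p.mu_s, p.g, p.n)
        entries[t] = p
    return OpticalTable(entries)


def _mc_reweighted_vector(head, layout, optics_base, optics_pert, cfg
                          ) -> MeasurementVector:
    """Tissue-perturbed MC measurements by reweighting the stored
    trajectories (identical photons: the mBLL shortcut)."""
    vec, records = mc_mod.assemble_measurement_vector(
        head, optics_base, layout, cfg.n_photons, seed=cfg.seed + 101, f=cfg.f,
        sds_max=cfg.sds_max, return_records=True)
    mu_pert = mc_mod.mu_a_volume(head, optics_pert)
    n_d = layout.n_d
    X = np.zeros(layout.n_s * n_d)
    Y = np.zeros(layout.n_s * n_d)
    nd = np.zeros(layout.n_s * n_d, int)
    for rec in records:
        ms = mc_mod.fd_measurement(rec, mu_pert, cfg.f, n_d)
        for j, m in enumerate(ms):
            X[rec.source_id * n_d + j] = m.X
            Y[rec.source_id * n_d + j] = m.Y
            nd[rec.source_id * n_d + j] = m.n_detected
    return MeasurementVector(X, Y, layout.sds_matrix().ravel(), layout.n_s,
                             n_d, f=cfg.f, n_detected=nd, sds_max=cfg.sds_max)
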