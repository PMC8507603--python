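"""Protocol orchestration: ensemble simulation -> kinetics -> orientation
modes -> umbrella/WHAM -> FEP -> contacts -> consistency report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import contacts as contacts_mod
from . import fep as fep_mod
from . import kinetics as kin
from . import orientation as ori
from .io import save_density_map, write_trajectory
from .toysim import (
    SimParams,
    build_bilayer,
    generate_lambda_set,
    generate_umbrella_windows,
    init_system,
    make_c2_like_body,
    simulate,
)
from .wham import WhamSettings, bootstrap_pmf, delta_pmf, wham, well_depth

logger = logging.getLogger("membind.pipeline")


@dataclass
class ProtocolConfig:
    """Everything needed to run the full toy protocol reproducibly."""

    membranes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "PC": {"PC": 1.0},
            "PC:PS": {"PC": 0.80, "PS": 0.20},
            "PC:PS:PIP2": {"PC": 0.80, "PS": 0.15, "PIP2": 0.05},
        }
    )
    n_lipids_per_leaflet: int = 80
    box_xy: tuple[float, float] = (7.0, 7.0)
    n_repeats: int = 25
    n_steps: int = 2000
    record_every: int = 10
    min_separation: float = 4.4
    sim: dict = field(default_factory=dict)  # SimParams overrides
    # kinetics
    on_cutoff: float = 0.5
    off_cutoff: float = 1.0
    min_dwell: int = 5
    # orientation modes
    distance_bin: float = 0.1
    rzz_bin: float = 0.05
    distance_bound: float = 3.0
    min_occupancy: float = 0.02
    # umbrella sampling / WHAM
    umbrella_z_min: float = 0.6
    umbrella_z_max: float = 7.0
    umbrella_spacing: float = 0.05
    umbrella_force_constant: float = 2000.0
    umbrella_n_samples: int = 5000
    umbrella_n_equil: int = 500
    wham_n_bootstrap: int = 20
    # FEP
    fep_n_states: int = 21
    fep_n_repeats: int = 5
    fep_n_samples: int = 1000
    # consistency pairing: PIP2-bearing membrane vs its PIP2->PC conversion
    pip2_membrane: str = "PC:PS:PIP2"
    ps_membrane: str = "PC:PS"
    base_seed: int = 1

    def sim_params(self, seed: int) -> SimParams:
        return SimParams(**{**self.sim, "seed": seed})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["box_xy"] = list(d["box_xy"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        if "box_xy" in d:
            d["box_xy"] = tuple(d["box_xy"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ProtocolConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name, seed=None):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = _time.perf_counter()
            logger.info("stage=%s status=start seed=%s", name, seed)
            out = fn(*args, **kwargs)
            logger.info(
                "stage=%s status=done wall_s=%.2f", name, _time.perf_counter() - t0
            )
            return out

        return wrapper

    return deco


def _converted_fractions(fractions: dict[str, float]) -> dict[str, float]:
    """Composition after converting all PIP2 head groups to PC."""
    out = dict(fractions)
    pip2 = out.pop("PIP2", 0.0)
    out["PC"] = out.get("PC", 0.0) + pip2
    return out


def simulate_ensemble(config: ProtocolConfig, label: str, outdir: Path | None = None):
    """Run the replica encounter simulations for one membrane."""
    fractions = config.membranes[label]
    body = make_c2_like_body()
    trajs = []
    for rep in range(config.n_repeats):
        seed = config.base_seed + rep
        bilayer = build_bilayer(
            config.n_lipids_per_leaflet, fractions, box_xy=config.box_xy, seed=seed
        )
        state = init_system(body, bilayer, config.min_separation, seed=seed)
        params = config.sim_params(seed)
        traj = simulate(
            state,
            params,
            n_steps=config.n_steps,
            record_every=config.record_every,
            use_upper_wall=True,
        )
        traj.metadata.update({"membrane": label, "repeat": rep, "seed": seed})
        if outdir is not None:
            write_trajectory(outdir / f"traj_{label.replace(':', '-')}_{rep}.h5", traj)
        trajs.append(traj)
    return trajs


def kinetics_stage(config: ProtocolConfig, trajs):
    series = [kin.min_distance_series(t) for t in trajs]
    segs = [
        kin.segment_events(
            s, config.on_cutoff, config.off_cutoff, config.min_dwell
        )
        for s in series
    ]
    mean = kin.ensemble_mean_distance(series)
    fit = kin.fit_exponential_decay(mean)
    return {
        "series": series,
        "segmentations": segs,
        "fraction_bound_mean": float(np.mean([s.fraction_bound for s in segs])),
        "n_events_total": int(sum(s.n_events for s in segs)),
        "decay_fit": dataclasses.asdict(fit),
    }


def modes_stage(config: ProtocolConfig, trajs):
    reference = ori.last_frame_reference(trajs)
    rzz = [ori.rzz_series(t, reference, "last-frame-of-first-repeat") for t in trajs]
    dist = [ori.com_z_distance_series(t) for t in trajs]
    dmap = ori.density_map(dist, rzz, config.distance_bin, config.rzz_bin)
    modes = ori.detect_modes(
        dmap, dist, rzz, config.distance_bound, config.min_occupancy
    )
    if modes:
        rzz = ori.rereference(trajs, modes[0])
        dmap = ori.density_map(dist, rzz, config.distance_bin, config.rzz_bin)
        modes = ori.detect_modes(
            dmap, dist, rzz, config.distance_bound, config.min_occupancy
        )
        modes = ori.score_modes(
            modes, trajs, physical_mask={"terminus": 0.5},
            productive_mask={"basic": 0.8},
            occupancy_threshold=config.min_occupancy,
        )
    return {"map": dmap, "modes": modes, "rzz": rzz, "dist": dist}


def pmf_stage(config: ProtocolConfig, label: str, fractions=None):
    """Mean-field umbrella sampling + WHAM for one composition."""
    fractions = fractions or config.membranes[label]
    body = make_c2_like_body()
    bilayer = build_bilayer(
        config.n_lipids_per_leaflet,
        fractions,
        box_xy=config.box_xy,
        seed=config.base_seed,
        mode="mean-field",
    )
    state = init_system(body, bilayer, config.min_separation, seed=config.base_seed)
    # locked, face-down orientation: the umbrella coordinate is COM z
    state.body_orientation = np.array([0.0, 0.0, 0.0, 1.0])
    params = config.sim_params(config.base_seed)
    centers = np.arange(
        config.umbrella_z_min,
        config.umbrella_z_max + 0.5 * config.umbrella_spacing,
        config.umbrella_spacing,
    )
    windows = generate_umbrella_windows(
        state,
        params,
        centers,
        force_constant=config.umbrella_force_constant,
        n_samples=config.umbrella_n_samples,
        n_equil=config.umbrella_n_equil,
        seed=config.base_seed,
    )
    settings = WhamSettings(
        bin_width=config.umbrella_spacing,
        temperature=params.temperature,
        n_bootstrap=config.wham_n_bootstrap,
        seed=config.base_seed,
    )
    profile = wham(windows, settings)
    profile.g_err = bootstrap_pmf(windows, settings)
    depth = well_depth(profile)
    return {"profile": profile, "depth": depth, "label": label}


def fep_stage(config: ProtocolConfig):
    """Sequential per-lipid PIP2->PC FEP on the mean-field system."""
    body = make_c2_like_body()
    fractions = config.membranes[config.pip2_membrane]
    params = config.sim_params(config.base_seed)
    base_bilayer = build_bilayer(
        config.n_lipids_per_leaflet,
        fractions,
        box_xy=config.box_xy,
        seed=config.base_seed,
        mode="mean-field",
    )
    n_pip2 = base_bilayer.species_counts.get("PIP2", 0)
    q_pip2 = base_bilayer.species_charges["PIP2"]
    per_repeat = np.zeros((config.fep_n_repeats, n_pip2))
    overlaps = []
    for rep in range(config.fep_n_repeats):
        counts = dict(base_bilayer.species_counts)
        for lip in range(n_pip2):
            bilayer = build_bilayer(
                config.n_lipids_per_leaflet,
                fractions,
                box_xy=config.box_xy,
                seed=config.base_seed,
                mode="mean-field",
            )
            bilayer.species_counts = dict(counts)
            state = init_system(body, bilayer, config.min_separation,
                                seed=config.base_seed)
            state.body_orientation = np.array([0.0, 0.0, 0.0, 1.0])
            seed = config.base_seed + 1000 * (rep + 1) + lip
            lset = generate_lambda_set(
                state, params, n_states=config.fep_n_states,
                n_samples=config.fep_n_samples, seed=seed,
            )
            result = fep_mod.multistate_free_energy(lset)
            free = generate_lambda_set(
                state, params, n_states=config.fep_n_states,
                n_samples=config.fep_n_samples, seed=seed + 1,
                include_protein=False,
            )
            dg_free = fep_mod.multistate_free_energy(free).delta_g
            ddg = fep_mod.binding_ddg(
                result.delta_g, dg_free, lset.lambdas, free.lambdas
            )
            per_repeat[rep, lip] = ddg.reported
            overlaps.append(float(result.overlap.min()))
            counts["PIP2"] -= 1
            counts["PC"] = counts.get("PC", 0) + 1
    fep_result = fep_mod.aggregate_repeats(per_repeat, overlap_diagnostics=overlaps)
    n_ions, species = fep_mod.counterion_neutralizer_count(q_pip2, 0.0)
    return {
        "result": fep_result,
        "counterions_per_lipid": n_ions,
        "counterion_species": species,
    }


def contacts_stage(config: ProtocolConfig, trajs, segs):
    traj = trajs[0]
    groups = {}
    for lab in sorted(set(traj.body.bead_labels)):
        groups[lab] = list(traj.body.beads_with_label(lab))
    species = [sp for sp, c in traj.bilayer.species_counts.items() if c > 0]
    freq = contacts_mod.contact_frequency(traj, groups, species, config.on_cutoff)
    out = {"contact_frequency": freq.as_dict()}
    if "PIP2" in species:
        mask = segs[0].bound_mask
        if mask.any():
            enr = contacts_mod.pip2_enrichment(
                traj, r_max=min(traj.bilayer.box_xy) * 0.45, n_bins=5,
                bound_mask=mask, cutoff=config.on_cutoff,
            )
            out["pip2_first_annulus_enrichment"] = float(enr.enrichment[0])
            out["pip2_mean_bound_count"] = enr.mean_bound_count
        counts = contacts_mod.basic_phosphate_contacts(traj, config.on_cutoff)
        out["mean_basic_phosphate_contacts"] = counts.mean
    return out


def run_protocol(config: ProtocolConfig, outdir) -> dict:
    """Execute all stages; returns the machine-readable report (also written
    to ``outdir/report.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "base_seed": config.base_seed,
            "config": config.to_dict(),
        },
        "membranes": {},
    }
    stage_names = []
    try:
        all_segs = {}
        all_trajs = {}
        for label in config.membranes:
            stage_names.append(f"simulate[{label}]")
            trajs = simulate_ensemble(config, label, outdir)
            all_trajs[label] = trajs
            stage_names.append(f"kinetics[{label}]")
            k = kinetics_stage(config, trajs)
            all_segs[label] = k["segmentations"]
            stage_names.append(f"modes[{label}]")
            m = modes_stage(config, trajs)
            save_density_map(
                outdir / f"map_{label.replace(':', '-')}.npz", m["map"]
            )
            report["membranes"][label] = {
                "fraction_bound": k["fraction_bound_mean"],
                "n_events": k["n_events_total"],
                "decay_fit": {
                    key: (None if isinstance(v, float) and not np.isfinite(v) else v)
                    for key, v in k["decay_fit"].items()
                },
                "modes": [
                    {
                        "center": list(mode.center),
                        "occupancy": mode.occupancy,
                        "flags": mode.flags,
                    }
                    for mode in m["modes"]
                ],
            }
        stage_names.append("pmf")
        pmf = {}
        for label in (config.pip2_membrane, config.ps_membrane):
            pmf[label] = pmf_stage(config, label)
        converted = _converted_fractions(config.membranes[config.pip2_membrane])
        pmf["converted"] = pmf_stage(config, "converted", fractions=converted)
        dp_headline = delta_pmf(
            pmf[config.pip2_membrane]["depth"].depth,
            pmf[config.ps_membrane]["depth"].depth,
            pmf[config.pip2_membrane]["depth"].error or 0.0,
            pmf[config.ps_membrane]["depth"].error or 0.0,
        )
        dp_matched = delta_pmf(
            pmf[config.pip2_membrane]["depth"].depth,
            pmf["converted"]["depth"].depth,
            pmf[config.pip2_membrane]["depth"].error or 0.0,
            pmf["converted"]["depth"].error or 0.0,
        )
        report["pmf"] = {
            label: {
                "well_depth": entry["depth"].depth,
                "well_location": entry["depth"].location,
                "well_depth_err": entry["depth"].error,
            }
            for label, entry in pmf.items()
        }
        report["pmf"]["delta_pmf"] = dataclasses.asdict(dp_headline)
        report["pmf"]["delta_pmf_converted"] = dataclasses.asdict(dp_matched)
        stage_names.append("fep")
        f = fep_stage(config)
        fep_result = f["result"]
        report["fep"] = {
            "per_lipid_ddg": fep_result.per_lipid_ddg,
            "per_lipid_err": fep_result.per_lipid_err,
            "total": fep_result.total,
            "total_err": fep_result.total_error,
            "n_repeats": fep_result.n_repeats,
            "counterions_per_lipid": f["counterions_per_lipid"],
            "counterion_species": f["counterion_species"],
        }
        stage_names.append("consistency")
        check = fep_mod.fep_pmf_consistency(
            fep_result, dp_matched.value, dp_matched.error
        )
        report["consistency"] = dataclasses.asdict(check)
        stage_names.append("contacts")
        label = config.pip2_membrane
        report["contacts"] = contacts_stage(
            config, all_trajs[label], all_segs[label]
        )
    except Exception as exc:
        stage = stage_names[-1] if stage_names else "setup"
        raise RuntimeError(
            f"protocol failed in stage {stage!r} "
            f"(base_seed={config.base_seed}): {exc}"
        ) from exc
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
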