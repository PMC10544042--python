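"""I/O, configuration and the experiment runner composing the whole study.

Volumes travel as NIfTI (spacing in the affine); calibrations as JSON;
experiment configurations as YAML; reports as CSV with one row per
(insert, method, dose, noise-reduction level) carrying the input-channel,
EAN/RED/SPR and range statistics of that condition, mirroring the structure
of the published noise tables.  A manifest records every seed so any report
row can be traced to its random stream.

The runner executes, per phantom: one extra calibration acquisition at
medium dose with no noise reduction (never reused for analysis), the
repeated noisy acquisitions per condition, the three mapping methods, ROI
statistics aggregated over repeats, and optionally the proton-range
simulation per insert.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import directspr_mapper as dsm
from . import ls_mapper as lsm
from . import naa_mapper as nam
from . import noise_range_analysis as nra
from . import phantom_sim as psim
from . import physics_core as pc
from . import vmi_optimizer as vopt

__all__ = [
    "ImageVolume",
    "ExperimentConfig",
    "read_volume",
    "write_volume",
    "save_calibration",
    "load_calibration",
    "run_experiment",
    "cli",
]


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D voxel grid with spacing and a free-text channel label."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    label: str = ""


def write_volume(volume: ImageVolume, path) -> None:
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), affine)
    img.header["descrip"] = volume.label.encode()[:79]
    nib.save(img, str(path))


def read_volume(path) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        label = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode()
    except Exception as exc:  # malformed file
        raise IOError(f"cannot read volume {path}: {exc}") from exc
    return ImageVolume(data=data, spacing_mm=spacing, label=label)


# ---------------------------------------------------------------------------
# calibration persistence
# ---------------------------------------------------------------------------


def save_calibration(calib, path, lut: lsm.LnILookup | None = None) -> None:
    """JSON round trip for LS / DirectSPR calibrations (+ optional lookup)."""
    if isinstance(calib, lsm.LSCalibration):
        doc = {"kind": "landry_saito", **dataclasses.asdict(calib)}
        if lut is not None:
            doc["lnI_lookup"] = {
                "x_breakpoints": list(map(float, lut.x_breakpoints)),
                "lnI_values": list(map(float, lut.lnI_values)),
                "m": lut.m,
            }
    elif isinstance(calib, dsm.AlphaCalibration):
        doc = {"kind": "directspr", **dataclasses.asdict(calib)}
    else:
        raise TypeError(f"unsupported calibration type {type(calib).__name__}")
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_calibration(path):
    """Returns the calibration dataclass (and the lookup for LS, if stored)."""
    try:
        doc = json.loads(Path(path).read_text())
        kind = doc.pop("kind")
    except (json.JSONDecodeError, KeyError) as exc:
        raise ValueError(f"malformed calibration file {path}: {exc}") from exc
    if kind == "landry_saito":
        lut_doc = doc.pop("lnI_lookup", None)
        calib = lsm.LSCalibration(**doc)
        if lut_doc is None:
            return calib
        lut = lsm.LnILookup(
            x_breakpoints=np.asarray(lut_doc["x_breakpoints"]),
            lnI_values=np.asarray(lut_doc["lnI_values"]),
            m=lut_doc["m"],
        )
        return calib, lut
    if kind == "directspr":
        return dsm.AlphaCalibration(**doc)
    raise ValueError(f"unknown calibration kind {kind!r} in {path}")


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

METHODS = ("naa", "ls", "directspr")


@dataclass(frozen=True)
class ExperimentConfig:
    """The full study design for one phantom size."""

    phantom: str = "Body"                      # Body | Head
    doses_mGy: tuple[float, ...] = (5.0, 10.0, 15.0)
    noise_reduction_levels: tuple[int, ...] = (0, 1, 2)
    methods: tuple[str, ...] = METHODS
    inserts: tuple[str, ...] = ()              # empty = all phantom inserts
    repeats: int = 30
    base_seed: int = 0
    height_mm: float = 50.0
    pair_assignment: dict = field(
        default_factory=lambda: dict(nam.default_pair_assignment().pairs)
    )
    noise: dict = field(default_factory=dict)  # NoiseModel field overrides
    range_simulation: bool = False
    range_height_mm: float = 110.0
    beam_energy_MeV: float = 105.0
    output_dir: str = "results"

    def __post_init__(self):
        if self.phantom not in ("Body", "Head"):
            raise ValueError(f"unknown phantom {self.phantom!r}")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("doses_mGy", "noise_reduction_levels", "methods", "inserts"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "pair_assignment" in raw:
            raw["pair_assignment"] = {
                k: tuple(v) for k, v in raw["pair_assignment"].items()
            }
        return ExperimentConfig(**raw)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["pair_assignment"] = {k: list(v) for k, v in doc["pair_assignment"].items()}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    def noise_model(self) -> psim.NoiseModel:
        defaults = {"dose_ref_mGy": 40.0 if self.phantom == "Head" else 10.0}
        defaults.update(self.noise)
        return psim.NoiseModel(**defaults)

    def phantom_spec(self, height: float | None = None) -> psim.PhantomSpec:
        make = psim.head_spec if self.phantom == "Head" else psim.body_spec
        return make(height_mm=self.height_mm if height is None else height)

    def medium_dose(self) -> float:
        doses = sorted(self.doses_mGy)
        return doses[len(doses) // 2]


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

_CAL_SEED_OFFSET = 900_001   # calibration acquisitions never share analysis seeds
_DOSE_SEED_STRIDE = 10_000   # distinct repeat streams per (dose, NR) condition


def _crop_bounds(mask: np.ndarray, margin: int, shape) -> tuple[slice, slice, slice]:
    idx = np.where(mask)
    return tuple(
        slice(max(0, int(i.min()) - margin), min(n, int(i.max()) + margin + 1))
        for i, n in zip(idx, shape)
    )


class _Stage:
    """Context tag so any failure is reported with its pipeline stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"experiment stage {self.name!r} failed: {exc}") from exc
        return False


def _calibrate_phantom(phantom, config: ExperimentConfig, noise, log):
    """The extra calibration acquisition: medium dose, no noise reduction."""
    insert_names = [i.material for i in phantom.spec.inserts]
    masks = {n: _insert_roi(phantom, n) for n in insert_names}
    acq = psim.AcquisitionSpec(
        ctdivol_mGy=config.medium_dose(), vmi_keV=(), include_native=True,
        noise_reduction=0, repeats=1,
        base_seed=config.base_seed + _CAL_SEED_OFFSET, noise=noise,
    )
    ch = psim.simulate_acquisition(phantom, acq, 0)
    mats = [
        pc.water() if n == "water" else pc.load_inserts()[n] for n in insert_names
    ]
    ct_low = np.array([ch[psim.KV_LOW][masks[n]].mean() for n in insert_names])
    ct_high = np.array([ch[psim.KV_HIGH][masks[n]].mean() for n in insert_names])
    ls_cal = lsm.calibrate_ls(ct_low, ct_high, mats, phantom_id=config.phantom)
    lut = lsm.build_lnI_lut(list(pc.load_tissues().values()), ls_cal.m)
    ds_cal = dsm.calibrate_alphas(ct_low, ct_high, mats, phantom_id=config.phantom)
    log(f"calibrated {config.phantom}: LS m={ls_cal.m:.3f} alpha={ls_cal.alpha:.3f}; "
        f"DirectSPR aRED={ds_cal.alpha_red:.3f}")
    return ls_cal, lut, ds_cal, acq.base_seed


def _insert_roi(phantom, insert_name, diameter=20.0, height=30.0):
    cx, cy = phantom.insert_center_mm(insert_name)
    dz = phantom.spacing_mm[2]
    nz = phantom.labels.shape[2]
    cz = dz * nz / 2.0
    return nra.cylinder_roi_mask(
        phantom.labels.shape, phantom.spacing_mm, (cx, cy, cz),
        diameter_mm=diameter, height_mm=min(height, dz * nz),
        origin_mm=(phantom.origin_mm[0], phantom.origin_mm[1], dz / 2.0),
    )


def _map_method(method, channels, crop, assignment, basis, ls_pack, ds_cal):
    """SPR (+ intermediates) for one method on a cropped region."""
    sl = crop
    if method == "naa":
        stack = {
            e: channels[e][sl]
            for e in assignment.energies() | {nam.TissueClassThresholds().reference_keV}
        }
        out = nam.map_spr_naa(stack, assignment, basis=basis)
        return {"SPR": out["SPR"], "EAN": out["EAN"], "RED": out["RED"]}
    if method == "ls":
        ls_cal, lut = ls_pack
        out = lsm.map_spr_ls(channels[psim.KV_LOW][sl], channels[psim.KV_HIGH][sl], ls_cal, lut)
        return {"SPR": out["SPR"], "RED": out["RED"]}
    out = dsm.map_spr_direct(channels[psim.KV_LOW][sl], channels[psim.KV_HIGH][sl], ds_cal)
    return {"SPR": out["SPR"]}


def _method_inputs(method, insert_class, assignment):
    """The two input channels whose noise the report row describes."""
    if method == "naa":
        return assignment[insert_class]
    return (psim.KV_LOW, psim.KV_HIGH)


def run_experiment(config: ExperimentConfig, log=None) -> pd.DataFrame:
    """Execute the full design; returns the report table and writes outputs.

    One row per (insert, method, dose, noise-reduction level) with
    input-channel / EAN / RED / SPR (and optionally range) statistics,
    each aggregated over the configured repeats.
    """
    t0 = time.time()
    messages: list[str] = []

    def _log(msg):
        messages.append(msg)
        if log is not None:
            log(msg)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    basis = pc.build_jh_basis()
    assignment = nam.PairAssignment(
        {k: tuple(v) for k, v in config.pair_assignment.items()}
    )
    noise = config.noise_model()

    with _Stage("phantom"):
        phantom = psim.build_phantom(config.phantom_spec())
        insert_names = list(config.inserts) or [
            i.material for i in phantom.spec.inserts
        ]
        rois = {n: _insert_roi(phantom, n) for n in insert_names}
        insert_classes = vopt.classify_tissues(
            {
                n: (pc.water() if n == "water" else pc.load_inserts()[n])
                for n in insert_names
            }
        )
        crops = {
            n: _crop_bounds(rois[n], 8, phantom.labels.shape) for n in insert_names
        }

    with _Stage("calibration"):
        ls_cal, lut, ds_cal, cal_seed = _calibrate_phantom(
            phantom, config, noise, _log
        )
        save_calibration(ls_cal, out_dir / f"ls_calibration_{config.phantom}.json", lut)
        save_calibration(ds_cal, out_dir / f"directspr_calibration_{config.phantom}.json")

    vmi_needed = tuple(
        sorted(assignment.energies() | {nam.TissueClassThresholds().reference_keV})
    )
    rows = []
    seeds_used = {"calibration": cal_seed}
    for di, dose in enumerate(config.doses_mGy):
        for li, level in enumerate(config.noise_reduction_levels):
            cond_seed = config.base_seed + _DOSE_SEED_STRIDE * (
                1 + di * len(config.noise_reduction_levels) + li
            )
            seeds_used[f"dose{dose}_nr{level}"] = cond_seed
            acq = psim.AcquisitionSpec(
                ctdivol_mGy=dose, vmi_keV=vmi_needed, include_native=True,
                noise_reduction=level, repeats=config.repeats,
                base_seed=cond_seed, noise=noise,
            )
            stats: dict = {}
            ranges: dict = {}
            with _Stage(f"acquisition dose={dose} nr={level}"):
                for rep in range(config.repeats):
                    channels = psim.simulate_acquisition(phantom, acq, rep)
                    for name in insert_names:
                        mask = rois[name]
                        crop = crops[name]
                        mask_c = mask[crop]
                        for method in config.methods:
                            maps = _map_method(
                                method, channels, crop, assignment, basis,
                                (ls_cal, lut), ds_cal,
                            )
                            key = (name, method)
                            e1, e2 = _method_inputs(
                                method, insert_classes[name], assignment
                            )
                            rec = stats.setdefault(key, {})
                            for qty, vol in (
                                ("mu_low", pc.hu_to_rel_atten(channels[e1][crop])),
                                ("mu_high", pc.hu_to_rel_atten(channels[e2][crop])),
                                *maps.items(),
                            ):
                                rec.setdefault(qty, []).append(
                                    nra.RoiStatsRecord.from_sample(
                                        vol[mask_c], quantity=qty
                                    )
                                )
            if config.range_simulation:
                with _Stage(f"range dose={dose} nr={level}"):
                    ranges = _range_simulation(config, noise, assignment, basis,
                                               (ls_cal, lut), ds_cal, insert_names,
                                               dose, level, cond_seed)
            for name in insert_names:
                for method in config.methods:
                    rec = stats[(name, method)]
                    row = {
                        "phantom": config.phantom, "dose_mGy": dose,
                        "noise_reduction": level, "insert": name,
                        "tissue_class": insert_classes[name], "method": method,
                        "repeats": config.repeats,
                    }
                    for qty, records in rec.items():
                        agg = nra.aggregate_repeats(records)
                        row[f"{qty.lower()}_mean"] = agg.mean
                        row[f"{qty.lower()}_ci87_pct"] = agg.ci87_pct
                        row[f"{qty.lower()}_skewness"] = agg.skewness
                    if (name, method) in ranges:
                        agg = ranges[(name, method)]
                        row["range_mean_mm"] = agg.mean
                        row["range_ci87_pct"] = agg.ci87_pct
                        row["range_skewness"] = agg.skewness
                    rows.append(row)
    report = pd.DataFrame(rows)

    with _Stage("report"):
        report_path = out_dir / f"report_{config.phantom}.csv"
        report.to_csv(report_path, index=False, float_format="%.6g")
        manifest = {
            "version": __version__,
            "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
            "seeds": seeds_used,
            "elapsed_s": round(time.time() - t0, 1),
            "log": messages,
        }
        (out_dir / f"manifest_{config.phantom}.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
    _log(f"report written: {report_path} ({len(report)} rows)")
    return report


def _range_simulation(config, noise, assignment, basis, ls_pack, ds_cal,
                      insert_names, dose, level, cond_seed):
    """Per-insert proton range statistics on a tall single-insert phantom.

    The acquisition noise is spatially white, so simulating a reduced
    field of view around each insert leaves all noise statistics unchanged
    while keeping the run affordable.
    """
    beam = nra.BeamSpec(energy_MeV=config.beam_energy_MeV)
    out = {}
    vmi_needed = tuple(
        sorted(assignment.energies() | {nam.TissueClassThresholds().reference_keV})
    )
    for name in insert_names:
        spec = psim.PhantomSpec(
            name=f"{config.phantom}-{name}-range",
            radii_mm=(30.0, 30.0), height_mm=config.range_height_mm,
            inserts=(psim.InsertSpec(name, (0.0, 0.0)),), margin_mm=4.0,
        )
        mini = psim.build_phantom(spec)
        center = (0.0, 0.0)  # the insert sits on the mini-phantom axis
        acq = psim.AcquisitionSpec(
            ctdivol_mGy=dose, vmi_keV=vmi_needed, include_native=True,
            noise_reduction=level, repeats=config.repeats,
            base_seed=cond_seed + 5000, noise=noise,
        )
        full = (slice(None),) * 3
        per_method: dict[str, list[np.ndarray]] = {m: [] for m in config.methods}
        for rep in range(config.repeats):
            channels = psim.simulate_acquisition(mini, acq, rep)
            for method in config.methods:
                spr = _map_method(
                    method, channels, full, assignment, basis, ls_pack, ds_cal
                )["SPR"]
                dose_grid, _ = nra.resample_to_dose_grid(spr, mini.spacing_mm, beam)
                r, _flagged = nra.simulate_range(dose_grid, beam, center, mini.origin_mm)
                per_method[method].append(r)
        for method in config.methods:
            try:
                out[(name, method)] = nra.range_statistics(per_method[method])
            except ValueError:
                pass  # beam exits the volume before R80 (e.g. lung): no range row
    return out


# ---------------------------------------------------------------------------
# command-line interface (thin wrappers over the library)
# ---------------------------------------------------------------------------


@click.group()
def cli():
    """Dual-energy CT proton SPR noise-sensitivity workbench."""


@cli.command()
@click.option("--phantom", type=click.Choice(["Body", "Head"]), default="Body")
@click.option("--dose", type=float, default=10.0, help="CTDIvol in mGy")
@click.option("--vmi", multiple=True, type=float, help="VMI energies (keV)")
@click.option("--repeat", type=int, default=0)
@click.option("--seed", type=int, default=0)
@click.option("--height", type=float, default=50.0)
@click.option("--out", type=click.Path(), required=True, help="output directory")
def simulate(phantom, dose, vmi, repeat, seed, height, out):
    """Simulate one noisy acquisition and write its channels as NIfTI."""
    config = ExperimentConfig(phantom=phantom, height_mm=height, base_seed=seed)
    ph = psim.build_phantom(config.phantom_spec())
    acq = psim.AcquisitionSpec(
        ctdivol_mGy=dose, vmi_keV=tuple(vmi), include_native=True,
        repeats=repeat + 1, base_seed=seed, noise=config.noise_model(),
    )
    channels = psim.simulate_acquisition(ph, acq, repeat)
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, vol in channels.items():
        label = f"{key:g}keV" if isinstance(key, float) else key
        write_volume(
            ImageVolume(vol, ph.spacing_mm, f"HU {label}"),
            out_dir / f"{phantom}_{label}.nii.gz".replace(".0keV", "keV"),
        )
    click.echo(f"wrote {len(channels)} channels to {out_dir}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), default="results")
@click.option("--phantom", type=click.Choice(["Body", "Head"]), default=None)
@click.option("--repeats", type=int, default=None)
@click.option("--range/--no-range", "range_sim", default=None)
def run(config_path, out, phantom, repeats, range_sim):
    """Run the full experiment (simulate, calibrate, map, analyze, report)."""
    config = (
        ExperimentConfig.from_yaml(config_path)
        if config_path
        else ExperimentConfig()
    )
    overrides = {"output_dir": out}
    if phantom:
        overrides["phantom"] = phantom
    if repeats:
        overrides["repeats"] = repeats
    if range_sim is not None:
        overrides["range_simulation"] = range_sim
    config = dataclasses.replace(config, **overrides)
    try:
        run_experiment(config, log=click.echo)
    except (ValueError, KeyError) as exc:
        raise SystemExit(f"configuration error: {exc}")


@cli.command()
@click.option("--phantom", type=click.Choice(["Body", "Head"]), default="Body")
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="results")
def calibrate(phantom, seed, out):
    """Calibrate the two kV-based methods on the synthetic phantom inserts."""
    config = ExperimentConfig(phantom=phantom, base_seed=seed, output_dir=out)
    ph = psim.build_phantom(config.phantom_spec())
    ls_cal, lut, ds_cal, _ = _calibrate_phantom(
        ph, config, config.noise_model(), click.echo
    )
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_calibration(ls_cal, out_dir / f"ls_calibration_{phantom}.json", lut)
    save_calibration(ds_cal, out_dir / f"directspr_calibration_{phantom}.json")
    click.echo(f"calibrations written to {out_dir}")


@cli.command()
@click.option("--step", type=float, default=5.0, help="energy grid step (keV)")
@click.option("--repeats", type=int, default=5)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="results/pair_ranking.csv")
def optimize(step, repeats, seed, out):
    """Rank VMI pairs by measured SPR RMSE pooled over both phantom sizes."""
    basis = pc.build_jh_basis()
    tissues = pc.load_tissues()
    energies = np.arange(40.0, 141.0, step)
    pairs = [
        (float(energies[i]), float(energies[j]))
        for i in range(len(energies))
        for j in range(i + 1, len(energies))
    ]
    scorer = vopt.PairScorer(tissues, basis, energies_keV=energies)
    theo = {c: scorer.rmse_many(pairs, c) for c in nam.TISSUE_CLASSES}
    inserts = pc.load_inserts()
    insert_classes = vopt.classify_tissues(inserts)
    measured = {c: np.zeros((2, repeats, len(pairs))) for c in nam.TISSUE_CLASSES}
    for ip, name in enumerate(("Body", "Head")):
        config = ExperimentConfig(phantom=name, base_seed=seed)
        ph = psim.build_phantom(config.phantom_spec())
        rois = {
            c: [
                (_insert_roi(ph, n), inserts[n])
                for n in inserts
                if insert_classes[n] == c
            ]
            for c in nam.TISSUE_CLASSES
        }
        acq = psim.AcquisitionSpec(
            ctdivol_mGy=config.medium_dose(), vmi_keV=tuple(energies),
            include_native=False, repeats=repeats, base_seed=seed + 777,
            noise=config.noise_model(),
        )
        for rep in range(repeats):
            channels = psim.simulate_acquisition(ph, acq, rep)
            for c in nam.TISSUE_CLASSES:
                for k, p in enumerate(pairs):
                    measured[c][ip, rep, k] = vopt.pair_rmse_measured(
                        p, channels, rois[c], basis
                    )
        click.echo(f"measured {name}")
    assignment, summaries = vopt.select_optimal(pairs, theo, measured)
    table = pd.concat(
        [df.assign(tissue_class=c) for c, df in summaries.items()],
        ignore_index=True,
    )
    Path(out).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, index=False, float_format="%.6g")
    click.echo(f"optimal pairs: {assignment.pairs}; ranking table: {out}")


@cli.command("map")
@click.option("--method", type=click.Choice(list(METHODS)), required=True)
@click.option("--low", type=click.Path(exists=True), help="low/E1 channel NIfTI")
@click.option("--high", type=click.Path(exists=True), help="high/E2 channel NIfTI")
@click.option("--calibration", type=click.Path(exists=True), default=None)
@click.option("--pair", nargs=2, type=float, default=None, help="VMI pair (keV)")
@click.option("--out", type=click.Path(), required=True, help="output SPR NIfTI")
def map_cmd(method, low, high, calibration, pair, out):
    """Map a low/high channel pair (files) to an SPR volume."""
    vol_low = read_volume(low)
    vol_high = read_volume(high)
    if method == "naa":
        if pair is None:
            raise SystemExit("--pair is required for the VMI method")
        basis = pc.build_jh_basis()
        e1, e2 = pair
        assignment = nam.PairAssignment(
            {"lung": (e1, e2), "soft": (e1, e2), "bone": (e1, e2)}
        )
        thresholds = nam.TissueClassThresholds(reference_keV=e1)
        stack = {e1: vol_low.data, e2: vol_high.data}
        spr = nam.map_spr_naa(stack, assignment, thresholds, basis)["SPR"]
    elif method == "ls":
        calib, lut = load_calibration(calibration)
        spr = lsm.map_spr_ls(vol_low.data, vol_high.data, calib, lut)["SPR"]
    else:
        calib = load_calibration(calibration)
        spr = dsm.map_spr_direct(vol_low.data, vol_high.data, calib)["SPR"]
    write_volume(ImageVolume(spr, vol_low.spacing_mm, f"SPR {method}"), out)
    click.echo(f"SPR map written to {out}")


@cli.command()
@click.option("--report", "report_path", type=click.Path(exists=True), required=True)
@click.option("--quantity", default="spr", help="column prefix, e.g. spr / red / range")
def summarize(report_path, quantity):
    """Print a condensed pivot of one quantity from a report CSV."""
    df = pd.read_csv(report_path)
    col = f"{quantity}_ci87_pct"
    if col not in df:
        raise SystemExit(f"no column {col} in {report_path}")
    pivot = df.pivot_table(
        index=["insert"], columns=["method", "dose_mGy"], values=col
    )
    click.echo(pivot.round(2).to_string())


if __name__ == "__main__":
    cli()
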