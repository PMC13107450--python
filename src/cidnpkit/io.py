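"""Readers, writers and the pipeline driver.

Tabular formats are tab-separated with ``#`` comment lines and mandatory
headers, chosen for unambiguous round-tripping:

* kinetic traces: columns ``time_us``, ``intensity`` and optional
  ``sigma``; a long format adds ``proton_label``;
* field profiles: column ``field_T`` followed by one signed-intensity
  column per proton; the conformer class travels in a
  ``# conformer_class: ...`` comment;
* diffusion decays: columns ``gradient``, ``intensity`` with the timing
  parameters in ``# key: value`` comments;
* coordinates: multi-frame XYZ or PDB (MODEL records), read through
  MDAnalysis, with moiety masks / donor quadruples / omega quadruples
  supplied as a plain ``key = atom names`` selection file.

Times are microseconds on disk and seconds in memory; fields tesla;
gradients T/m (G/cm accepted via an explicit unit tag); coordinates
angstrom.
"""

from __future__ import annotations

import io as _io
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diffusion import DiffusionDecay, gradient_to_si
from .errors import ParseError, ValidationError
from .geometry import LabeledFrame
from .kinetics import KineticTrace
from .spin import FieldProfile

logger = logging.getLogger("cidnpkit")

__all__ = [
    "read_trace",
    "read_traces",
    "write_trace",
    "write_traces",
    "read_profiles",
    "write_profiles",
    "read_decay",
    "write_decay",
    "read_masks",
    "read_frames",
    "PipelineConfig",
    "run_pipeline",
]


def _read_table(path, required, optional=()):
    path = Path(path)
    if not path.exists():
        raise ParseError("file does not exist", path=str(path))
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # malformed TSV
        raise ParseError(f"cannot parse TSV: {exc}", path=str(path)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns {missing}", path=str(path))
    for col in list(required) + [c for c in optional if c in df.columns]:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"non-numeric value in column {col!r}",
                path=str(path),
                line=int(bad[0]) + 2,
            )
        if df[col].isna().any():
            line = int(df.index[df[col].isna()][0]) + 2
            raise ParseError(
                f"missing value in column {col!r} (truncated file?)",
                path=str(path),
                line=line,
            )
    return df


def _comment_metadata(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for raw in fh:
            if not raw.startswith("#"):
                break
            body = raw[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


# --------------------------------------------------------------------------
# kinetic traces
# --------------------------------------------------------------------------

def write_trace(trace: KineticTrace, path) -> None:
    """One-proton TSV: ``# proton_label`` comment + time_us/intensity/sigma."""
    with open(path, "w") as fh:
        fh.write(f"# proton_label: {trace.proton_label}\n")
        cols = ["time_us", "intensity"] + (["sigma"] if trace.sigma is not None else [])
        fh.write("\t".join(cols) + "\n")
        for i in range(trace.times.size):
            row = [f"{trace.times[i] * 1e6:.10g}", f"{trace.intensities[i]:.10g}"]
            if trace.sigma is not None:
                row.append(f"{trace.sigma[i]:.10g}")
            fh.write("\t".join(row) + "\n")


def read_trace(path) -> KineticTrace:
    df = _read_table(path, required=("time_us", "intensity"), optional=("sigma",))
    meta = _comment_metadata(path)
    times = df["time_us"].to_numpy(float) * 1e-6
    if times.size and not np.all(np.diff(times) > 0):
        bad = int(np.argmin(np.diff(times) > 0))
        raise ParseError("time_us not strictly increasing", path=str(path), line=bad + 3)
    logger.debug("read %s: times converted us -> s", path)
    try:
        return KineticTrace(
            proton_label=meta.get("proton_label", Path(path).stem),
            times=times,
            intensities=df["intensity"].to_numpy(float),
            sigma=df["sigma"].to_numpy(float) if "sigma" in df.columns else None,
        )
    except ValidationError as exc:
        raise ParseError(str(exc), path=str(path)) from exc


def write_traces(traces: Sequence[KineticTrace], path) -> None:
    """Long-format TSV with a proton_label column."""
    with open(path, "w") as fh:
        has_sigma = all(t.sigma is not None for t in traces)
        cols = ["proton_label", "time_us", "intensity"] + (["sigma"] if has_sigma else [])
        fh.write("\t".join(cols) + "\n")
        for t in traces:
            for i in range(t.times.size):
                row = [t.proton_label, f"{t.times[i] * 1e6:.10g}", f"{t.intensities[i]:.10g}"]
                if has_sigma:
                    row.append(f"{t.sigma[i]:.10g}")
                fh.write("\t".join(row) + "\n")


def read_traces(path) -> list[KineticTrace]:
    """Read either a one-proton file or a long-format multi-proton file."""
    df = _read_table(path, required=("time_us", "intensity"), optional=("sigma",))
    if "proton_label" not in df.columns:
        return [read_trace(path)]
    out = []
    for lab, sub in df.groupby("proton_label", sort=False):
        times = sub["time_us"].to_numpy(float) * 1e-6
        try:
            out.append(
                KineticTrace(
                    proton_label=str(lab),
                    times=times,
                    intensities=sub["intensity"].to_numpy(float),
                    sigma=sub["sigma"].to_numpy(float) if "sigma" in df.columns else None,
                )
            )
        except ValidationError as exc:
            raise ParseError(f"trace {lab!r}: {exc}", path=str(path)) from exc
    return out


# --------------------------------------------------------------------------
# field profiles
# --------------------------------------------------------------------------

def write_profiles(profiles: Sequence[FieldProfile], path) -> None:
    if not profiles:
        raise ValidationError("no profiles to write")
    ref = profiles[0].fields
    for p in profiles[1:]:
        if p.fields.shape != ref.shape or not np.allclose(p.fields, ref):
            raise ValidationError("all profiles in one file must share the field grid")
    with open(path, "w") as fh:
        fh.write(f"# conformer_class: {profiles[0].conformer_class}\n")
        fh.write("\t".join(["field_T"] + [p.proton_label for p in profiles]) + "\n")
        for i in range(ref.size):
            fh.write(
                "\t".join(
                    [f"{ref[i]:.10g}"] + [f"{p.intensities[i]:.10g}" for p in profiles]
                )
                + "\n"
            )


def read_profiles(path) -> list[FieldProfile]:
    df = _read_table(path, required=("field_T",))
    meta = _comment_metadata(path)
    conformer = meta.get("conformer_class", "unassigned")
    fields = df["field_T"].to_numpy(float)
    if not np.all(np.diff(fields) > 0):
        bad = int(np.argmin(np.diff(fields) > 0))
        raise ParseError("field_T not strictly increasing", path=str(path), line=bad + 3)
    out = []
    for col in df.columns:
        if col == "field_T":
            continue
        try:
            out.append(
                FieldProfile(
                    proton_label=col,
                    fields=fields.copy(),
                    intensities=df[col].to_numpy(float),
                    conformer_class=conformer,
                )
            )
        except ValidationError as exc:
            raise ParseError(f"profile {col!r}: {exc}", path=str(path)) from exc
    if not out:
        raise ParseError("no intensity columns found", path=str(path))
    return out


# --------------------------------------------------------------------------
# diffusion decays
# --------------------------------------------------------------------------

def write_decay(decay: DiffusionDecay, path, gradient_unit: str = "T/m") -> None:
    g = decay.gradients if gradient_unit == "T/m" else decay.gradients / gradient_to_si(
        np.array([1.0]), gradient_unit
    )[0]
    with open(path, "w") as fh:
        fh.write(f"# gradient_unit: {gradient_unit}\n")
        fh.write(f"# big_delta_ms: {decay.big_delta * 1e3:.10g}\n")
        fh.write(f"# little_delta_ms: {decay.little_delta * 1e3:.10g}\n")
        fh.write(f"# gyromagnetic_ratio: {decay.gyromagnetic_ratio:.10g}\n")
        fh.write("gradient\tintensity\n")
        for i in range(g.size):
            fh.write(f"{g[i]:.10g}\t{decay.intensities[i]:.10g}\n")


def read_decay(path) -> DiffusionDecay:
    df = _read_table(path, required=("gradient", "intensity"))
    meta = _comment_metadata(path)
    unit = meta.get("gradient_unit", "T/m")
    g = gradient_to_si(df["gradient"].to_numpy(float), unit)
    if unit != "T/m":
        logger.debug("read %s: gradients converted %s -> T/m", path, unit)
    try:
        return DiffusionDecay(
            gradients=g,
            intensities=df["intensity"].to_numpy(float),
            big_delta=float(meta.get("big_delta_ms", 50.0)) * 1e-3,
            little_delta=float(meta.get("little_delta_ms", 2.0)) * 1e-3,
            gyromagnetic_ratio=float(meta.get("gyromagnetic_ratio", 2.6752218744e8)),
        )
    except ValidationError as exc:
        raise ParseError(str(exc), path=str(path)) from exc


# --------------------------------------------------------------------------
# coordinates
# --------------------------------------------------------------------------

def read_masks(path) -> dict:
    """Selection file: ``key = name1 name2 ...`` per line, '#' comments.

    Required keys: ``F`` and ``W`` (moiety atom names).  Optional:
    ``donor``/``donor2``/... (four names N H O C) and ``omega1``/``omega2``/...
    (four names defining each proline's peptide-bond dihedral, flavin-first).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError("file does not exist", path=str(path))
    sel: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError("expected 'key = names...'", path=str(path), line=ln)
            key, names = line.split("=", 1)
            key = key.strip()
            if key in sel:
                raise ParseError(f"duplicate key {key!r}", path=str(path), line=ln)
            sel[key] = names.split()
    for key in ("F", "W"):
        if key not in sel:
            raise ParseError(f"selection file must define {key!r}", path=str(path))
    return sel


def _indices(names_in_frame: list[str], wanted: list[str], path, key) -> list[int]:
    index = {}
    for i, nm in enumerate(names_in_frame):
        index.setdefault(nm, i)
    out = []
    for nm in wanted:
        if nm not in index:
            raise ParseError(f"atom {nm!r} of selection {key!r} not present", path=str(path))
        out.append(index[nm])
    return out


def read_frames(traj_path, masks) -> list[LabeledFrame]:
    """Read a multi-frame XYZ or PDB file into labeled frames.

    ``masks`` is a selection dict (see :func:`read_masks`) or a path to a
    selection file.
    """
    import MDAnalysis as mda

    if not isinstance(masks, dict):
        masks = read_masks(masks)
    traj_path = Path(traj_path)
    if not traj_path.exists():
        raise ParseError("file does not exist", path=str(traj_path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(traj_path))
        names = [str(n) for n in u.atoms.names]
        try:
            residues = [str(r) for r in u.atoms.resnames]
        except (mda.exceptions.NoDataError, AttributeError):
            residues = ["UNK"] * len(names)

        f_idx = _indices(names, masks["F"], traj_path, "F")
        w_idx = _indices(names, masks["W"], traj_path, "W")
        donor_keys = sorted(k for k in masks if k.startswith("donor"))
        omega_keys = sorted(k for k in masks if k.startswith("omega"))
        donors = [tuple(_indices(names, masks[k], traj_path, k)) for k in donor_keys]
        omegas = [tuple(_indices(names, masks[k], traj_path, k)) for k in omega_keys]
        for k, quad in zip(donor_keys + omega_keys, donors + omegas):
            if len(quad) != 4:
                raise ParseError(
                    f"selection {k!r} must list exactly four atoms", path=str(traj_path)
                )

        frames = []
        for ts in u.trajectory:
            frames.append(
                LabeledFrame(
                    atom_names=list(names),
                    residue_labels=list(residues),
                    coordinates=np.array(ts.positions, dtype=float),
                    moiety_masks={"F": np.array(f_idx), "W": np.array(w_idx)},
                    donor_quads=list(donors),
                    omega_atom_quads=list(omegas),
                )
            )
    if not frames:
        raise ParseError("trajectory contains no frames", path=str(traj_path))
    return frames


def write_frames_xyz(frames: Sequence[LabeledFrame], path) -> None:
    """Multi-frame XYZ (atom names as element column)."""
    with open(path, "w") as fh:
        for k, fr in enumerate(frames):
            fh.write(f"{len(fr.atom_names)}\n")
            fh.write(f"frame {k}\n")
            for nm, (x, y, z) in zip(fr.atom_names, fr.coordinates):
                fh.write(f"{nm} {x:.6f} {y:.6f} {z:.6f}\n")


# --------------------------------------------------------------------------
# pipeline configuration and driver
# --------------------------------------------------------------------------

_CONFIG_KEYS = {
    "seed",
    "stages",
    "n_replicates",
    "noise_level",
    "pulse_us",
    "delays_us",
    "kinetic_truth",
    "field_truth",
    "ensemble",
    "diffusion_truth",
    "classifier",
    "log_level",
}


@dataclass
class PipelineConfig:
    """Declarative configuration of :func:`run_pipeline`.

    Unknown keys are rejected; ``from_dict`` / ``to_dict`` round-trip
    losslessly.
    """

    seed: int = 0
    stages: tuple[str, ...] = ()
    n_replicates: int = 1
    noise_level: float = 0.05
    pulse_us: float = 4.0
    delays_us: tuple[float, ...] = (0.0, 3.0, 100.0)
    kinetic_truth: dict = field(default_factory=lambda: {"kt_R0": 1e5, "T1": 120e-6})
    field_truth: dict = field(default_factory=lambda: {"mechanism": "J_BIRADICAL", "peak_field": 13e-3})
    ensemble: dict = field(
        default_factory=lambda: {"n_frames": 2000, "stacked_fraction": 0.20, "hbond_fraction": 0.05}
    )
    diffusion_truth: dict = field(default_factory=lambda: {"D": 5e-10})
    classifier: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValidationError(f"unknown configuration keys {sorted(unknown)}")
        kwargs = dict(data)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "delays_us" in kwargs:
            kwargs["delays_us"] = tuple(kwargs["delays_us"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        d["delays_us"] = list(d["delays_us"])
        return d

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested all-synthetic stages under one seed.

    Stages: ``kinetics`` (simulate + refit), ``field`` (synthesize +
    classify), ``geometry`` (ensemble + statistics), ``diffusion``
    (decay + fit).  Returns one JSON-serializable report with a block per
    executed stage; an empty stage list yields an empty report.
    """
    from . import fitting, geometry, spin, synthetic  # local import to avoid cycles

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    valid = {"kinetics", "field", "geometry", "diffusion"}
    unknown = set(config.stages) - valid
    if unknown:
        raise ValidationError(f"unknown pipeline stages {sorted(unknown)}")

    root = np.random.SeedSequence(config.seed)
    stage_seeds = {s: ss for s, ss in zip(sorted(valid), root.spawn(len(valid)))}
    report: dict = {"seed": config.seed, "stages": {}}

    if "kinetics" in config.stages:
        from .kinetics import KineticParameters, PulseTiming

        params = KineticParameters(
            kt_R0=float(config.kinetic_truth.get("kt_R0", 1e5)),
            T1=float(config.kinetic_truth.get("T1", 120e-6)),
        )
        pulse = PulseTiming(config.pulse_us * 1e-6)
        delays = np.asarray(config.delays_us, float) * 1e-6
        seeds = stage_seeds["kinetics"].spawn(config.n_replicates)
        fits = []
        for ss in seeds:
            trace, _ = synthetic.gen_kinetic_trace(
                params, delays, pulse, noise_level=config.noise_level, seed=ss
            )
            res = fitting.fit_kinetics(trace, pulse, fitting.FitSpec(seed=config.seed))
            fits.append(res.estimates)
        report["stages"]["kinetics"] = {
            "truth": {"kt_R0": params.kt_R0, "T1": params.T1},
            "n_replicates": config.n_replicates,
            "median_estimates": {
                k: float(np.median([f[k] for f in fits])) for k in fits[0]
            },
        }

    if "field" in config.stages:
        truth = dict(config.field_truth)
        profiles, trecord = synthetic.gen_field_profiles(
            truth.get("mechanism", "J_BIRADICAL"),
            proton_labels=truth.get("protons", ["F8p", "W6", "W2"]),
            peak_field=float(truth.get("peak_field", 13e-3)),
            seed=stage_seeds["field"],
        )
        call = spin.classify_mechanism(
            profiles, spin.ClassifierThresholds(**config.classifier)
        )
        report["stages"]["field"] = {
            "truth": trecord,
            "call": {
                "label": call.label.value,
                "peak_field": call.peak_field,
                "sign_uniformity": call.sign_uniformity,
                "highfield_ratio": call.highfield_ratio
                if np.isfinite(call.highfield_ratio)
                else None,
            },
        }

    if "geometry" in config.stages:
        frames, truth = synthetic.gen_conformer_ensemble(
            n_frames=int(config.ensemble.get("n_frames", 2000)),
            stacked_fraction=float(config.ensemble.get("stacked_fraction", 0.20)),
            hbond_fraction=float(config.ensemble.get("hbond_fraction", 0.05)),
            label_distribution=config.ensemble.get("label_distribution"),
            seed=stage_seeds["geometry"],
        )
        stats = geometry.ensemble_statistics(frames)
        report["stages"]["geometry"] = {
            "truth": {
                "stacked_fraction": truth.stacked_fraction,
                "hbond_fraction": truth.hbond_fraction,
            },
            "pooled": {
                "p_stacked": stats.pooled.p_stacked,
                "p_hbond": stats.pooled.p_hbond,
                "n_frames": stats.pooled.n_frames,
            },
            "label_fractions": stats.label_fractions,
        }

    if "diffusion" in config.stages:
        from .diffusion import stejskal_tanner_fit

        decay, truth = synthetic.gen_diffusion_decay(
            D=float(config.diffusion_truth.get("D", 5e-10)),
            seed=stage_seeds["diffusion"],
        )
        fit = stejskal_tanner_fit(decay)
        report["stages"]["diffusion"] = {
            "truth": truth,
            "fit": {"D": fit.D, "I0": fit.I0, "D_stderr": fit.D_stderr},
        }

    return report
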