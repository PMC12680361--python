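"""Readers/writers for the plain-text parameter-file dialects, time-course
CSV, result serialisation and run manifests.

Parameter files carry one numeric value per line in a fixed documented
order (15 slots for kinetics, 21 for the initial substrate/cocktail
configuration).  Comment lines — any line whose leading token is not
numeric — are tolerated anywhere, as is a tolerant ``name value`` dialect.
Hard parameter ranges raise; excursions outside the typical ranges only
warn.

Percentages are 0-100 at every I/O boundary and 0-1 internally.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import TimeCourse
from .engine import Trajectory
from .kinetics import CocktailConfig, KineticParams
from .substrate import Composition, ConfigurationError, SubstrateConfig

__all__ = [
    "ParameterFile",
    "SchemaError",
    "read_parameter_file",
    "write_parameter_file",
    "kinetic_params_from_file",
    "substrate_from_file",
    "read_timecourses",
    "write_timecourses",
    "trajectory_to_frame",
    "write_trajectories",
    "write_manifest",
]


class SchemaError(ValueError):
    """Parameter file does not match its schema."""


#: (slot name, hard range or None, typical range or None)
KINETIC_SCHEMA = (
    ("EG Kcat", (0.0, np.inf), (0.001, 1000.0)),
    ("EG Km", (0.0, np.inf), (0.001, 1000.0)),
    ("CBH processive digestion rate", (0.0, np.inf), (10.0, 10000.0)),
    ("BGL Kcat", (0.0, np.inf), (0.001, 1000.0)),
    ("BGL Km", (0.0, np.inf), (0.001, 1000.0)),
    ("XYL Kcat", (0.0, np.inf), (0.001, 1000.0)),
    ("XYL Km", (0.0, np.inf), (0.001, 1000.0)),
    ("CBH Kcat (attachment reaction)", (0.0, np.inf), (0.001, 1000.0)),
    ("CBH Km (attachment reaction)", (0.0, np.inf), (0.001, 1000.0)),
    ("omega EG cbs", (0.0, 1.0), None),
    ("omega CBH cbs", (0.0, 1.0), None),
    ("omega EG glc", (0.0, 1.0), None),
    ("omega CBH glc", (0.0, 1.0), None),
    ("omega BGL glc", (0.0, 1.0), None),
    ("Enzyme size: radius", (0.0, np.inf), (1.0, 25.0)),
)

INITIAL_CONFIG_SCHEMA = (
    ("mode_code", (1.0, 5.0), None),
    ("pct_EG", (0.0, 1.0), None),
    ("pct_CBH", (0.0, 1.0), None),
    ("pct_BGL", (0.0, 1.0), None),
    ("pct_XYL", (0.0, 1.0), None),
    ("total_enz_molecules", (0.0, np.inf), (1.0, 10000.0)),
    ("length_fibril", (2.0, np.inf), (10.0, 2000.0)),
    ("boolean_Xyl_or_MLG", (0.0, 1.0), None),
    ("pct_xyl", (0.0, 1.0), None),
    ("pct_cellu", (0.0, 1.0), (0.01, 1.0)),
    ("pct_hemi", (0.0, 1.0), (0.0, 1.0)),
    ("pct_lign", (0.0, 1.0), (0.0, 1.0)),
    ("pct_acetyl_hemi", (0.0, 1.0), None),
    ("pct_crystalline_cellu", (0.0, 1.0), None),
    ("pct_crystalline_hemi", (0.0, 1.0), None),
    ("Mean_defect_size", (0.0, 0.5), None),
    ("Nbr_of_defects", (0.0, 1.0), None),
    ("r_monomer", (0.0, np.inf), (0.3, 1.0)),
    ("Lignin_adhesion_rate", (0.0, np.inf), (100.0, 350.0)),
    ("digestibility_ratio cellu", (0.0, 1.0), (1e-5, 1.0)),
    ("digestibility_ratio hemi", (0.0, 1.0), (1e-5, 1.0)),
)

SCHEMAS = {"kinetic": KINETIC_SCHEMA, "initial_configuration": INITIAL_CONFIG_SCHEMA}


@dataclass
class ParameterFile:
    """Ordered numeric values parsed from one text parameter file."""

    values: list[float]
    schema: str
    source: str = ""


def _parse_value(line: str) -> float | None:
    tokens = line.replace("=", " ").split()
    if not tokens:
        return None
    try:
        return float(tokens[0])
    except ValueError:
        pass
    # tolerant `name value` dialect
    if len(tokens) >= 2:
        try:
            return float(tokens[-1])
        except ValueError:
            return None
    return None


def read_parameter_file(path: str | Path, schema: str) -> ParameterFile:
    """Parse a parameter file against the named schema.

    Raises :class:`SchemaError` naming the first missing slot if the value
    count is short, and :class:`ConfigurationError` on hard-range
    violations; warns on typical-range excursions.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    slots = SCHEMAS[schema]
    path = Path(path)
    values: list[float] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "//", ";")):
            continue
        v = _parse_value(line)
        if v is not None and len(values) < len(slots):
            values.append(v)
    if len(values) < len(slots):
        name = slots[len(values)][0]
        raise SchemaError(
            f"{path}: expected {len(slots)} values for schema {schema!r}, "
            f"got {len(values)}; first missing slot is #{len(values) + 1} ({name})"
        )
    for v, (name, hard, typical) in zip(values, slots):
        if hard is not None and not hard[0] <= v <= hard[1]:
            raise ConfigurationError(
                f"{path}: {name} = {v} outside hard range [{hard[0]}, {hard[1]}]"
            )
        if typical is not None and not typical[0] <= v <= typical[1]:
            warnings.warn(
                f"{path}: {name} = {v} outside typical range [{typical[0]}, {typical[1]}]",
                stacklevel=2,
            )
    return ParameterFile(values=values, schema=schema, source=str(path))


def write_parameter_file(path: str | Path, pf: ParameterFile) -> None:
    """Write values first, slot-name comments at the bottom."""
    slots = SCHEMAS[pf.schema]
    if len(pf.values) != len(slots):
        raise SchemaError(f"{len(pf.values)} values for {len(slots)}-slot schema {pf.schema!r}")
    lines = [repr(float(v)) for v in pf.values]
    lines.append("")
    for k, (name, _, _) in enumerate(slots, start=1):
        lines.append(f"# parameter #{k}: {name}")
    Path(path).write_text("\n".join(lines) + "\n")


def kinetic_params_from_file(path: str | Path) -> KineticParams:
    v = read_parameter_file(path, "kinetic").values
    return KineticParams(
        kcat_EG=v[0],
        Km_EG=v[1],
        k_CBH_proc=v[2],
        kcat_BGL=v[3],
        Km_BGL=v[4],
        kcat_XYL=v[5],
        Km_XYL=v[6],
        kcat_CBH_attach=v[7],
        Km_CBH_attach=v[8],
        omega_EG_cbs=v[9],
        omega_CBH_cbs=v[10],
        omega_EG_glc=v[11],
        omega_CBH_glc=v[12],
        omega_BGL_glc=v[13],
        r_enzyme=v[14],
    )


def substrate_from_file(
    path: str | Path, free_floating: bool = False, sample_id: str | None = None
) -> tuple[SubstrateConfig, CocktailConfig]:
    """Build substrate and cocktail configurations from the 21-slot file."""
    v = read_parameter_file(path, "initial_configuration").values
    comp = Composition(
        pct_cellulose=v[9],
        pct_hemicellulose=v[10],
        pct_lignin=v[11],
        pct_acetate=v[12],
        sample_id=sample_id or Path(path).stem,
    )
    config = SubstrateConfig(
        composition=comp,
        mode_code=int(v[0]),
        length_fibril=int(v[6]),
        CF_cellu=v[13],
        CF_hemi=v[14],
        mu_defect=v[15],
        N_defect=v[16],
        r_monomer=v[17],
        lignin_adhesion_rate=v[18],
        r_ca_cellu=v[19],
        r_ca_hemi=v[20],
        free_floating=free_floating,
        hemi_is_xylan=bool(round(v[7])),
    )
    cocktail = CocktailConfig(
        pct_EG=v[1], pct_CBH=v[2], pct_BGL=v[3], pct_XYL=v[4], total_enz_molecules=v[5]
    )
    return config, cocktail


# ---------------------------------------------------------------------------
# time-courses and trajectories
# ---------------------------------------------------------------------------

TIMECOURSE_COLUMNS = ("time_h", "value_pct", "sample_id", "replicate")


def read_timecourses(path: str | Path) -> list[TimeCourse]:
    """Load a tidy time-course CSV (time_h, value_pct, sample_id,
    replicate) into per-sample :class:`TimeCourse` objects."""
    df = pd.read_csv(path)
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df.value_pct.lt(0).any() or df.value_pct.gt(100).any():
        bad = df[(df.value_pct < 0) | (df.value_pct > 100)].iloc[0]
        raise ValueError(f"{path}: value {bad.value_pct} outside [0, 100]")
    dup = df.duplicated(subset=["sample_id", "replicate", "time_h"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate timestamp {row.time_h} for sample "
            f"{row.sample_id!r} replicate {row.replicate!r}"
        )
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        piv = grp.pivot_table(
            index="replicate", columns="time_h", values="value_pct"
        ).sort_index(axis=1)
        out.append(
            TimeCourse(
                sample_id=str(sid),
                times=piv.columns.to_numpy(dtype=float),
                values=piv.to_numpy(dtype=float),
                replicates=[str(r) for r in piv.index],
            )
        )
    return out


def write_timecourses(path: str | Path, timecourses: list[TimeCourse]) -> None:
    rows = []
    for tc in timecourses:
        for rep, vals in zip(tc.replicates, tc.values):
            for t, v in zip(tc.times, vals):
                rows.append(
                    {"time_h": t, "value_pct": v, "sample_id": tc.sample_id, "replicate": rep}
                )
    pd.DataFrame(rows, columns=list(TIMECOURSE_COLUMNS)).to_csv(path, index=False)


def trajectory_to_frame(tr: Trajectory, replicate: int | str = 0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_h": tr.times,
            "glucose": tr.glucose,
            "cellobiose": tr.cellobiose,
            "xylose": tr.xylose,
            "conversion_pct": tr.conversion,
            "replicate": replicate,
        }
    )


def write_trajectories(path: str | Path, trajectories: list[Trajectory]) -> None:
    frames = [trajectory_to_frame(tr, k) for k, tr in enumerate(trajectories)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


def _config_payload(obj) -> dict:
    if hasattr(obj, "__dataclass_fields__"):
        return json.loads(json.dumps(asdict(obj), default=str))
    return {"repr": repr(obj)}


def write_manifest(path: str | Path, command: str, seed, **objects) -> dict:
    """Emit a JSON manifest describing one run (command, seed, parameter
    payloads and their hash, package version, timestamp)."""
    from . import __version__

    payload = {name: _config_payload(obj) for name, obj in objects.items()}
    blob = json.dumps(payload, sort_keys=True).encode()
    manifest = {
        "command": command,
        "seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "parameters": payload,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
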