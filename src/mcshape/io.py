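"""File formats: spectra, titration series, shift tables, configs, reports.

Spectra are two-column comma-separated text (``frequency_hz,intensity``)
with a ``# key=value`` metadata header; the reader tolerates blank lines
and comments.  A titration series is a directory of slice files plus a
key=value sidecar recording every parameter and the seed.  Run
configuration is a single YAML file whose physical quantities carry
explicit unit suffixes in their keys (k1_off_per_s, omega_PL_hz, P0_M)
to keep unit errors loud.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import ExchangeScheme, KineticRow, MixComposition
from .lineshape import AcquisitionSettings, SpinParameters, Spectrum1D
from .titration import CSPRecord, TitrationSeries

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_series",
    "read_series",
    "read_shift_table",
    "write_csp_records",
    "read_kinetic_table",
    "write_ground_truth",
    "read_ground_truth",
    "write_fit_report",
    "load_config",
    "scheme_from_config",
    "spin_from_config",
    "acq_from_config",
    "mix_from_config",
]

_FLOAT_META = {
    "equivalents", "P0_M", "L0_M", "k1_on_per_M_s", "k1_off_per_s", "k2_per_s",
    "k2_prime_per_s", "omega_P_hz", "omega_PL_hz", "R2_per_s", "echo_time_s",
    "noise_sigma", "spectral_width_hz",
}


def _parse_meta_value(key: str, raw: str):
    raw = raw.strip()
    if key in _FLOAT_META:
        return float(raw)
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


def write_spectrum(spectrum: Spectrum1D, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in sorted(spectrum.metadata.items())]
    lines.append("frequency_hz,intensity")
    for f, y in zip(spectrum.frequency, spectrum.intensity):
        # repr precision: text round-trip must reproduce the floats exactly
        lines.append(f"{f:.17g},{y:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> Spectrum1D:
    path = Path(path)
    meta: dict = {}
    freqs: list[float] = []
    ys: list[float] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = _parse_meta_value(k.strip(), v)
            continue
        if line.startswith("frequency_hz"):
            continue
        a, b = line.split(",")
        freqs.append(float(a))
        ys.append(float(b))
    if not freqs:
        raise ValueError(f"{path}: no data rows")
    return Spectrum1D(np.array(freqs), np.array(ys), meta)


def write_series(series: TitrationSeries, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for eq, spec in series:
        p = directory / f"slice_eq{eq:07.3f}.csv"
        write_spectrum(spec, p)
        paths.append(p)
    meta = dict(series.metadata)
    meta["P0_M"] = series.P0
    (directory / "series.txt").write_text(
        "\n".join(f"{k}={v}" for k, v in sorted(meta.items())) + "\n"
    )
    return paths


def read_series(directory: str | Path) -> TitrationSeries:
    directory = Path(directory)
    files = sorted(directory.glob("slice_eq*.csv"))
    if not files:
        raise FileNotFoundError(f"no slice_eq*.csv files in {directory}")
    points = []
    for p in files:
        spec = read_spectrum(p)
        eq = spec.metadata.get("equivalents")
        if eq is None:
            raise ValueError(f"{p}: missing 'equivalents' metadata")
        points.append((float(eq), spec))
    points.sort(key=lambda t: t[0])
    meta = {}
    sidecar = directory / "series.txt"
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = _parse_meta_value(k.strip(), v)
    P0 = meta.get("P0_M") or points[0][1].metadata.get("P0_M")
    if P0 is None:
        raise ValueError(f"{directory}: P0_M found in neither sidecar nor slice metadata")
    return TitrationSeries(points, P0=float(P0), metadata=meta)


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Delimited text with header residue,dH,dN[,assigned]."""
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    if "assigned" in df.columns:
        df["assigned"] = df["assigned"].map(
            lambda v: str(v).strip().lower() in ("1", "true", "yes")
        )
    return df


def write_csp_records(records: list[CSPRecord], path: str | Path) -> None:
    lines = ["residue,csp_ppm,bin"]
    lines += [f"{r.residue},{r.csp:.6g},{r.bin}" for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


def read_kinetic_table(path: str | Path) -> list[KineticRow]:
    """Delimited text with header peptide,k_on,k_off."""
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    return [
        KineticRow(peptide=str(r["peptide"]), k_on=float(r["k_on"]), k_off=float(r["k_off"]))
        for _, r in df.iterrows()
    ]


def write_ground_truth(truth, path: str | Path) -> None:
    s, sp, acq = truth.scheme, truth.spin, truth.acq
    kv = {
        "label": truth.label,
        "k1_on_per_M_s": s.k1_on,
        "k1_off_per_s": s.k1_off,
        "k2_per_s": s.k2,
        "k2_prime_per_s": s.k2_prime,
        "omega_P_hz": sp.omega_P,
        "omega_PL_hz": sp.omega_PL,
        "R2_per_s": sp.R2,
        "echo_time_s": sp.echo_time,
        "P0_M": truth.P0,
        "equivalents_grid": ",".join(f"{e:g}" for e in truth.grid),
        "spectral_width_hz": acq.spectral_width,
        "n_points": acq.n_points,
        "zero_fill_factor": acq.zero_fill_factor,
        "apodization": acq.apodization,
        "noise_sigma": truth.noise_sigma,
        "noise_domain": truth.noise_domain,
        "seed": truth.seed,
    }
    Path(path).write_text("\n".join(f"{k}={v}" for k, v in kv.items()) + "\n")


def read_ground_truth(path: str | Path):
    from .synthetic import GroundTruth

    kv = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
    return GroundTruth(
        scheme=ExchangeScheme(
            k1_on=float(kv["k1_on_per_M_s"]),
            k1_off=float(kv["k1_off_per_s"]),
            k2=float(kv["k2_per_s"]),
            k2_prime=float(kv["k2_prime_per_s"]),
        ),
        spin=SpinParameters(
            omega_P=float(kv["omega_P_hz"]),
            omega_PL=float(kv["omega_PL_hz"]),
            R2=float(kv["R2_per_s"]),
            echo_time=float(kv["echo_time_s"]),
        ),
        P0=float(kv["P0_M"]),
        grid=tuple(float(x) for x in kv["equivalents_grid"].split(",")),
        acq=AcquisitionSettings(
            spectral_width=float(kv["spectral_width_hz"]),
            n_points=int(kv["n_points"]),
            zero_fill_factor=int(kv["zero_fill_factor"]),
            apodization=kv["apodization"],
        ),
        noise_sigma=float(kv.get("noise_sigma", 0.0)),
        noise_domain=kv.get("noise_domain", "frequency"),
        seed=int(kv.get("seed", 0)),
        label=kv.get("label", ""),
    )


def write_fit_report(result, path: str | Path, extra: dict | None = None) -> None:
    """key=value blocks per parameter: value, bound-hit and flat flags."""
    from . import __version__

    lines = [
        f"# mcshape {__version__} fit report",
        f"objective={result.objective:.8g}",
        f"objective_kind={result.config.objective_kind}",
        f"converged_starts={result.n_starts_converged}",
        f"seed={result.config.seed}",
    ]
    if extra:
        lines += [f"{k}={v}" for k, v in extra.items()]
    for name, value in sorted(result.params.items()):
        lines.append(f"[{name}]")
        lines.append(f"value={value:.8g}")
        lines.append(f"free={name in result.config.free}")
        if name in result.config.free:
            lines.append(f"bound_hit={result.bound_hit[name]}")
            lines.append(f"flat_direction={result.identifiability[name]}")
    Path(path).write_text("\n".join(lines) + "\n")


# --- YAML run configuration ------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def scheme_from_config(cfg: dict) -> ExchangeScheme:
    block = cfg["scheme"]
    return ExchangeScheme(
        k1_on=float(block["k1_on_per_M_s"]),
        k1_off=float(block["k1_off_per_s"]),
        k2=float(block.get("k2_per_s", 0.0)),
        k2_prime=float(block.get("k2_prime_per_s", 0.0)),
    )


def spin_from_config(cfg: dict) -> SpinParameters:
    block = cfg["spin"]
    return SpinParameters(
        omega_P=float(block["omega_P_hz"]),
        omega_PL=float(block["omega_PL_hz"]),
        R2=float(block["R2_per_s"]),
        echo_time=float(block.get("echo_time_s", 0.011)),
    )


def acq_from_config(cfg: dict) -> AcquisitionSettings:
    block = cfg.get("acquisition", {})
    return AcquisitionSettings(
        spectral_width=float(block.get("spectral_width_hz", 4000.0)),
        n_points=int(block.get("n_points", 2048)),
        zero_fill_factor=int(block.get("zero_fill_factor", 2)),
        apodization=block.get("apodization", "cosine-bell-shifted"),
    )


def mix_from_config(cfg: dict) -> MixComposition:
    block = cfg["mix"]
    if "L0_M" in block:
        L0 = float(block["L0_M"])
    else:
        L0 = float(block["equivalents"]) * float(block["P0_M"])
    return MixComposition(P0=float(block["P0_M"]), L0=L0)
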