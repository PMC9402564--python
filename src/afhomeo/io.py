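"""Config parsing and deterministic table writers.

Tables are tab-separated with 12-significant-digit, locale-independent
formatting so repeated runs are byte-identical and usable as regression
golden files.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    DispersionGeometry,
    LengthDistribution,
    ModelParams,
    dispersion_coefficients_closed_form,
    force_law,
)

__all__ = [
    "CONFIG_KEYS",
    "load_config",
    "write_distribution_table",
    "read_distribution_table",
    "write_manifest",
    "file_checksum",
    "get_logger",
]

# key -> coercion; mirrors the ModelParams fields settable from a config file
CONFIG_KEYS = {
    "N": int,
    "T": float,
    "V": float,
    "lam": float,
    "a": int,
    "f0": float,
    "l0": float,
    "kb": float,
    "kb_ratio": float,
    "m": int,
}

TABLE_COLUMNS = [
    "class_index",
    "length",
    "A_coeff",
    "force_N",
    "exponent_dispersion",
    "exponent_force",
    "probability",
    "monomer_count",
    "filament_count",
]


def get_logger(include_timestamps: bool = True) -> logging.Logger:
    """Package logger; timestamps can be disabled for stable golden logs."""
    logger = logging.getLogger("afhomeo")
    if not logger.handlers:
        handler = logging.StreamHandler()
        fmt = "%(asctime)s %(levelname)s %(message)s" if include_timestamps \
            else "%(levelname)s %(message)s"
        handler.setFormatter(logging.Formatter(fmt))
        logger.addHandler(handler)
    return logger


def load_config(path) -> ModelParams:
    """Parse a flat key=value config file into ModelParams.

    Missing keys fall back to the reference defaults; unknown keys are
    rejected with the list of valid keys; blank lines and ``#`` comments
    are ignored.
    """
    text = Path(path).read_text()
    overrides: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(
                f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in CONFIG_KEYS:
            raise ValueError(
                f"{path}:{lineno}: unknown key {key!r}; valid keys: "
                + ", ".join(sorted(CONFIG_KEYS)))
        try:
            coerce = CONFIG_KEYS[key]
            v = value.strip()
            overrides[key] = coerce(float(v)) if coerce is int else coerce(v)
            if coerce is int and float(v) != overrides[key]:
                raise ValueError
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: could not parse {value.strip()!r} "
                f"as {CONFIG_KEYS[key].__name__} for key {key!r}") from None
    return ModelParams(**overrides)


def _fmt(x: float) -> str:
    """12 significant digits, period decimal separator."""
    return f"{x:.11e}"


def write_distribution_table(dist: LengthDistribution, params: ModelParams,
                             geom: DispersionGeometry | None,
                             path, overwrite: bool = False) -> Path:
    """Write one distribution as a TSV with documented column order.

    Columns: class_index, length, A_coeff, force_N, exponent_dispersion,
    exponent_force, probability, monomer_count, filament_count. Floats are
    printed with 12 significant digits; the file ends with a newline.
    Refuses to overwrite an existing file unless told to.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(
            f"{path} exists; pass overwrite=True (or --overwrite) to replace")
    if geom is None:
        geom = dispersion_coefficients_closed_form(params.a, params.m)
    m = dist.m
    lengths = np.arange(1, m + 1)
    force = force_law(lengths, params)
    filament = dist.filament_counts()
    lines = ["\t".join(TABLE_COLUMNS)]
    for i in range(m):
        lines.append("\t".join([
            str(i + 1),
            str(int(lengths[i])),
            str(int(geom.A[i])),
            _fmt(force[i]),
            _fmt(dist.exponent_dispersion[i]),
            _fmt(dist.exponent_force[i]),
            _fmt(dist.p[i]),
            _fmt(dist.n[i]),
            _fmt(filament[i]),
        ]))
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing distribution table to {path}: {exc}"
                      ) from exc
    return path


def read_distribution_table(path) -> pd.DataFrame:
    """Read a distribution TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t")


def file_checksum(path) -> str:
    """SHA-256 of a file's bytes (hex)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(entries, path, overwrite: bool = False) -> Path:
    """Write a sweep manifest: one row (file, param, value, checksum).

    ``entries`` is an iterable of (file_path, param_name, value) triples;
    checksums are computed from the files so a re-run can be verified
    byte-for-byte.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(
            f"{path} exists; pass overwrite=True (or --overwrite) to replace")
    lines = ["file\tparam\tvalue\tchecksum"]
    for file_path, param, value in entries:
        fval = value if isinstance(value, str) else _fmt(float(value))
        lines.append("\t".join([
            Path(file_path).name, param, fval, file_checksum(file_path)]))
    path.write_text("\n".join(lines) + "\n")
    return path
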