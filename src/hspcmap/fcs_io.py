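"""FCS file I/O, channel resolution and pipeline configuration.

The reader/writer covers list-mode FCS as the pipeline needs it: version
2.0/3.0/3.1 headers, a single data set, float (``$DATATYPE F``/``D``) or
unsigned-integer (``I``) storage, either byte order. Files are written as
FCS 3.1, float32, little-endian — lossless for the synthetic data and
round-trippable by the module's own reader.

Marker resolution follows vendor practice: the stain keyword ``$PnS`` is
tried first, then the short parameter name ``$PnN``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .channels import CHANNELS, GROUP_COL, PATIENT_COL
from .errors import ChannelMapError, ConfigError, FormatError, GateError
from .pregating import PolygonGate
from .similarity_classify import GridSpec
from .transform_embed import EmbedParams

__all__ = [
    "ChannelMap",
    "read_events",
    "write_events",
    "load_config",
    "PipelineConfig",
]

_HEADER_LEN = 58
_DELIM = b"/"


@dataclass(frozen=True)
class ChannelMap:
    """Mapping from analysis marker names to FCS parameter names.

    The default identity map expects parameters named exactly like the
    analysis channels (the convention of this package's own writer).
    """

    mapping: dict[str, str] = field(
        default_factory=lambda: {ch: ch for ch in CHANNELS}
    )

    def resolve(self, pns: list[str], pnn: list[str]) -> dict[str, int]:
        """Resolve every analysis marker to a parameter index ($PnS, then $PnN)."""
        out: dict[str, int] = {}
        unresolved = []
        for marker, target in self.mapping.items():
            if target in pns:
                out[marker] = pns.index(target)
            elif target in pnn:
                out[marker] = pnn.index(target)
            else:
                unresolved.append(marker)
        if unresolved:
            raise ChannelMapError(
                f"could not resolve marker(s) {unresolved} to any FCS parameter"
            )
        return out


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    parts = raw[1:].split(delim)
    # trailing delimiter produces an empty tail entry
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FormatError("TEXT segment has an odd number of tokens")
    text = {}
    for i in range(0, len(parts), 2):
        key = parts[i].decode("utf-8", "replace").strip().upper()
        text[key] = parts[i + 1].decode("utf-8", "replace").strip()
    return text


def _read_header_offsets(header: bytes) -> tuple[int, int, int, int]:
    def _field(a: int, b: int) -> int:
        s = header[a:b].decode("ascii", "replace").strip()
        return int(s) if s else 0

    return _field(10, 18), _field(18, 26), _field(26, 34), _field(34, 42)


def read_events(path: str | Path, channel_map: ChannelMap | None = None) -> pd.DataFrame:
    """Read an FCS file into an event table restricted to analysis channels.

    Event order is preserved and the row count equals ``$TOT``. Columns are
    renamed to the analysis marker names of the channel map.
    """
    channel_map = channel_map or ChannelMap()
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_LEN or not raw[:3] == b"FCS":
        raise FormatError(f"{path}: not an FCS file")
    try:
        t0, t1, d0, d1 = _read_header_offsets(raw)
        text = _parse_text_segment(raw[t0 : t1 + 1])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: corrupt FCS header/TEXT segment: {exc}") from exc

    if int(text.get("$BEGINDATA", 0) or 0):
        d0, d1 = int(text["$BEGINDATA"]), int(text["$ENDDATA"])

    try:
        tot = int(text["$TOT"])
        par = int(text["$PAR"])
        datatype = text["$DATATYPE"].upper()
        byteord = text["$BYTEORD"]
    except KeyError as exc:
        raise FormatError(f"{path}: missing required keyword {exc}") from exc

    endian = "<" if byteord.startswith("1") else ">"
    bits = {int(text.get(f"$P{i + 1}B", 32)) for i in range(par)}
    if len(bits) != 1:
        raise FormatError(f"{path}: mixed $PnB widths unsupported: {sorted(bits)}")
    nbits = bits.pop()
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        dtype = np.dtype(f"{endian}u{nbits // 8}")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = tot * par * dtype.itemsize
    data = raw[d0 : d0 + expected]
    if len(data) != expected:
        raise FormatError(
            f"{path}: data segment truncated ({len(data)} bytes, expected {expected})"
        )
    matrix = np.frombuffer(data, dtype=dtype).reshape(tot, par).astype(np.float64)

    pnn = [text.get(f"$P{i + 1}N", "") for i in range(par)]
    pns = [text.get(f"$P{i + 1}S", "") for i in range(par)]
    idx = channel_map.resolve(pns, pnn)
    return pd.DataFrame({marker: matrix[:, j] for marker, j in idx.items()})


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    """Write an event table as FCS 3.1 (float32, list mode, little-endian).

    All numeric columns except the patient/group annotations are written as
    parameters, with both ``$PnN`` and ``$PnS`` set to the column name.
    """
    cols = [c for c in table.columns if c not in (PATIENT_COL, GROUP_COL)]
    if len(table) == 0 or not cols:
        raise ValueError("cannot write an empty event table")
    matrix = table[cols].to_numpy(dtype=np.float32)
    n, p = matrix.shape
    data_bytes = matrix.astype("<f4").tobytes()

    kw: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "%010d"),
        ("$ENDDATA", "%010d"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$TOT", str(n)),
        ("$PAR", str(p)),
    ]
    for i, name in enumerate(cols):
        rng = float(np.nanmax(matrix[:, i])) if n else 0.0
        kw += [
            (f"$P{i + 1}N", str(name)),
            (f"$P{i + 1}S", str(name)),
            (f"$P{i + 1}B", "32"),
            (f"$P{i + 1}E", "0,0"),
            (f"$P{i + 1}R", str(int(max(rng, 1)) + 1)),
        ]

    def _render(begin_data: int, end_data: int) -> bytes:
        buf = io.BytesIO()
        buf.write(_DELIM)
        for key, val in kw:
            if val == "%010d":
                val = "%010d" % (begin_data if key == "$BEGINDATA" else end_data)
            buf.write(key.encode() + _DELIM + val.encode() + _DELIM)
        return buf.getvalue()

    text_start = _HEADER_LEN
    text_len = len(_render(0, 0))  # offsets are fixed-width: length is stable
    data_start = text_start + text_len
    data_end = data_start + len(data_bytes) - 1
    text = _render(data_start, data_end)
    text_end = text_start + len(text) - 1

    def _fmt(v: int) -> bytes:
        s = str(v) if v <= 99_999_999 else "0"
        return s.rjust(8).encode()

    header = b"FCS3.1    " + b"".join(
        _fmt(v) for v in (text_start, text_end, data_start, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    Path(path).write_bytes(header + text + data_bytes)


# --------------------------------------------------------------------------
# Pipeline configuration


def _default_config_dict() -> dict:
    return {
        "pregate": {
            "cell_cap": 1000,
            "doublet_max_deviation": 0.3,
            "viability_threshold": 1000.0,
            "cd34_threshold": 300.0,
            "gates": {
                "fsc_ssc": {
                    "x_channel": "FSC-A",
                    "y_channel": "SSC-A",
                    "vertices": [
                        [15000, 0], [160000, 0], [160000, 90000], [15000, 90000],
                    ],
                },
                "cd45_ssc": {
                    "x_channel": "CD45",
                    "y_channel": "SSC-A",
                    "vertices": [
                        [200, 0], [50000, 0], [50000, 90000], [200, 90000],
                    ],
                },
                "goi": {
                    "x_channel": "CD34",
                    "y_channel": "SSC-A",
                    "vertices": [
                        [100, 0], [400000, 0], [400000, 80000], [100, 80000],
                    ],
                },
            },
        },
        "cohort": {
            "n_cr": 12,
            "n_ad": 9,
            "cells_per_patient": [2000, 50000],
            "doublet_fraction": 0.05,
            "dead_fraction": 0.05,
        },
        "transform": {"cofactor": 150.0},
        "embed": {"perplexity": 70, "n_iter": 3000, "pca_dims": 50, "seed": 0},
        "thresholds": {
            "positive": {"CD34": 300.0, "CD38": 300.0, "CD45RA": 300.0,
                         "CD123": 300.0, "PD-L1": 300.0},
            "cd123_low_upper": 2000.0,
        },
        "grid": {"n_bins": 100, "padding": 0.02, "smooth_bins": 1.0},
        "classify": {"tie_tol": 1e-9},
        "tsne_gates": {},
    }


@dataclass
class PipelineConfig:
    """Validated configuration for every pipeline stage."""

    cell_cap: int
    doublet_max_deviation: float
    viability_threshold: float
    cd34_threshold: float
    scatter_gate: PolygonGate
    cd45_gate: PolygonGate
    goi_gate: PolygonGate
    cofactor: float
    embed: EmbedParams
    raw_positive_thresholds: dict[str, float]
    raw_cd123_low_upper: float
    grid: GridSpec
    tie_tol: float
    tsne_gates: dict[str, list[list[float]]]
    cohort: dict
    raw_dict: dict


def _merge(defaults: dict, override: dict, path: str, bad: list[str]) -> dict:
    out = dict(defaults)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            bad.append(here)
        elif isinstance(defaults[key], dict) and key != "tsne_gates":
            if not isinstance(val, dict):
                bad.append(here)
            else:
                out[key] = _merge(defaults[key], val, here, bad)
        else:
            out[key] = val
    return out


def _gate_from_dict(name: str, spec: dict) -> PolygonGate:
    return PolygonGate(
        name=name,
        x_channel=spec["x_channel"],
        y_channel=spec["y_channel"],
        vertices=tuple((v[0], v[1]) for v in spec["vertices"]),
    )


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML/JSON config, filling unspecified keys with defaults.

    ``None`` or an empty file yields the full default configuration.
    Unknown keys and malformed gates raise :class:`ConfigError` naming the
    offending keys.
    """
    override: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        override = loaded

    bad: list[str] = []
    cfg = _merge(_default_config_dict(), override, "", bad)
    if bad:
        raise ConfigError(f"unknown or malformed config key(s): {bad}")

    try:
        gates = {}
        for name, spec in cfg["pregate"]["gates"].items():
            try:
                gates[name] = _gate_from_dict(name, spec)
            except (GateError, KeyError, TypeError) as exc:
                raise ConfigError(f"pregate.gates.{name}: {exc}") from exc
        for name, verts in cfg["tsne_gates"].items():
            try:
                _gate_from_dict(name, {"x_channel": "tSNE1", "y_channel": "tSNE2",
                                       "vertices": verts})
            except (GateError, KeyError, TypeError) as exc:
                raise ConfigError(f"tsne_gates.{name}: {exc}") from exc
        embed = EmbedParams(
            perplexity=float(cfg["embed"]["perplexity"]),
            n_iter=int(cfg["embed"]["n_iter"]),
            pca_dims=int(cfg["embed"]["pca_dims"]),
            seed=int(cfg["embed"]["seed"]),
        )
        grid = GridSpec(
            n_bins=int(cfg["grid"]["n_bins"]),
            padding=float(cfg["grid"]["padding"]),
            smooth_bins=float(cfg["grid"]["smooth_bins"]),
        )
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config value: {exc}") from exc

    return PipelineConfig(
        cell_cap=int(cfg["pregate"]["cell_cap"]),
        doublet_max_deviation=float(cfg["pregate"]["doublet_max_deviation"]),
        viability_threshold=float(cfg["pregate"]["viability_threshold"]),
        cd34_threshold=float(cfg["pregate"]["cd34_threshold"]),
        scatter_gate=gates["fsc_ssc"],
        cd45_gate=gates["cd45_ssc"],
        goi_gate=gates["goi"],
        cofactor=float(cfg["transform"]["cofactor"]),
        embed=embed,
        raw_positive_thresholds={k: float(v) for k, v in cfg["thresholds"]["positive"].items()},
        raw_cd123_low_upper=float(cfg["thresholds"]["cd123_low_upper"]),
        grid=grid,
        tie_tol=float(cfg["classify"]["tie_tol"]),
        tsne_gates={k: [list(map(float, v)) for v in verts]
                    for k, verts in cfg["tsne_gates"].items()},
        cohort=dict(cfg["cohort"]),
        raw_dict=cfg,
    )
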