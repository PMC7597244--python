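"""File formats: CSV impedance tables, network files, SPICE netlists.

The exchange format for spectra is a comma-separated table with a mandatory
header ``frequency_hz,re_z_ohm,im_z_ohm`` and strictly ascending
frequencies.  Valsa networks round-trip through a plain text file, one
element per line.  Emulator circuits export as generic SPICE3 netlists (one
``.subckt`` per CPE network plus the three ladder resistors), and
``evaluate_netlist`` re-parses such a netlist and solves it by modified
nodal analysis — an independent path used to validate the closed-form
impedance routines.
"""

from __future__ import annotations

import logging
import re
from typing import List, Optional, Tuple, Union

import numpy as np

from .circuits import (
    EmulatedTissueModel,
    FrequencyGrid,
    ImpedanceSpectrum,
    ValsaNetwork,
)

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_network",
    "write_network",
    "export_netlist",
    "evaluate_netlist",
]

logger = logging.getLogger(__name__)

_HEADER = "frequency_hz,re_z_ohm,im_z_ohm"


def write_spectrum(spectrum: ImpedanceSpectrum, path) -> None:
    """Write a spectrum as CSV; 15 significant digits for round-tripping."""
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for f, z in zip(spectrum.frequencies, spectrum.values):
            fh.write(f"{f:.15g},{z.real:.15g},{z.imag:.15g}\n")


def read_spectrum(path) -> ImpedanceSpectrum:
    """Read a CSV impedance table; malformed rows raise with line numbers."""
    freqs: List[float] = []
    re_z: List[float] = []
    im_z: List[float] = []
    n_blank = 0
    with open(path) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != _HEADER:
            raise ValueError(
                f"{path}: expected header {_HEADER!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            stripped = line.strip()
            if not stripped:
                n_blank += 1
                continue
            parts = stripped.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                f, re_v, im_v = (float(p) for p in parts)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if not all(np.isfinite([f, re_v, im_v])):
                raise ValueError(f"{path}:{lineno}: non-finite value")
            freqs.append(f)
            re_z.append(re_v)
            im_z.append(im_v)
    if n_blank:
        logger.warning("%s: skipped %d blank lines", path, n_blank)
    if len(freqs) >= 2 and np.any(np.diff(freqs) <= 0):
        raise ValueError(f"{path}: frequencies must be strictly ascending")
    return ImpedanceSpectrum(np.asarray(freqs), np.asarray(re_z) + 1j * np.asarray(im_z))


# --- plain network files ----------------------------------------------------


def write_network(network: ValsaNetwork, path) -> None:
    """One element per line: label, value, unit."""
    with open(path, "w") as fh:
        fh.write(f"R0 {network.r_p:.15g} ohm\n")
        fh.write(f"C0 {network.c_p:.15g} farad\n")
        for k, (r, c) in enumerate(network.branches, start=1):
            fh.write(f"R{k} {r:.15g} ohm\n")
            fh.write(f"C{k} {c:.15g} farad\n")


def read_network(path) -> ValsaNetwork:
    values = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'label value unit'")
            values[parts[0].upper()] = float(parts[1])
    m = max(int(k[1:]) for k in values if k.startswith("R"))
    return ValsaNetwork(
        r_p=values["R0"],
        c_p=values["C0"],
        branches=tuple((values[f"R{k}"], values[f"C{k}"]) for k in range(1, m + 1)),
    )


# --- SPICE netlists ---------------------------------------------------------

_SUFFIXES = (
    (1e9, "G"), (1e6, "MEG"), (1e3, "k"), (1.0, ""),
    (1e-3, "m"), (1e-6, "u"), (1e-9, "n"), (1e-12, "p"), (1e-15, "f"),
)
_SUFFIX_VALUES = {
    "g": 1e9, "meg": 1e6, "k": 1e3, "m": 1e-3, "u": 1e-6,
    "n": 1e-9, "p": 1e-12, "f": 1e-15, "": 1.0,
}


def _format_value(value: float) -> str:
    for scale, suffix in _SUFFIXES:
        if value >= scale:
            return f"{value / scale:.6g}{suffix}"
    return f"{value:.6g}"


def _parse_value(token: str) -> float:
    m = re.fullmatch(r"([0-9.eE+-]+)(meg|[gkmunpf]?)", token, flags=re.IGNORECASE)
    if not m:
        raise ValueError(f"cannot parse SPICE value {token!r}")
    return float(m.group(1)) * _SUFFIX_VALUES[m.group(2).lower()]


def _subckt_lines(name: str, network: ValsaNetwork) -> List[str]:
    lines = [f".subckt {name} a b"]
    lines.append(f"R0 a b {_format_value(network.r_p)}")
    lines.append(f"C0 a b {_format_value(network.c_p)}")
    for k, (r, c) in enumerate(network.branches, start=1):
        lines.append(f"R{k} a n{k} {_format_value(r)}")
        lines.append(f"C{k} n{k} b {_format_value(c)}")
    lines.append(f".ends {name}")
    return lines


def export_netlist(
    circuit: Union[EmulatedTissueModel, ValsaNetwork], path=None
) -> str:
    """Emit a SPICE3 netlist; the one-port is between nodes ``in`` and 0.

    Output is a deterministic function of the circuit (identical inputs give
    identical bytes).  If ``path`` is given the text is also written there.
    """
    lines = ["* dentimp tissue-emulator netlist"]
    if isinstance(circuit, ValsaNetwork):
        lines += _subckt_lines("cpe_net", circuit)
        lines.append("Xnet in 0 cpe_net")
    else:
        lines += _subckt_lines("cpe_s", circuit.network_s)
        lines += _subckt_lines("cpe_d", circuit.network_d)
        lines.append(f"Rss in n1 {_format_value(circuit.r_ss)}")
        lines.append("Xs n1 0 cpe_s")
        lines.append(f"Rs n1 n2 {_format_value(circuit.r_s)}")
        lines.append("Xd n2 0 cpe_d")
        lines.append(f"Rd n2 0 {_format_value(circuit.r_d)}")
    lines.append(".end")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _flatten_netlist(text: str) -> List[Tuple[str, str, str, float]]:
    """Expand subcircuits; return (kind, node_a, node_b, value) cards."""
    subckts = {}
    top: List[Tuple[str, List[str]]] = []
    current: Optional[str] = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("*"):
            continue
        tokens = line.split()
        lower = tokens[0].lower()
        if lower == ".subckt":
            current = tokens[1]
            subckts[current] = {"ports": tokens[2:], "cards": []}
        elif lower == ".ends":
            current = None
        elif lower == ".end":
            break
        elif current is not None:
            subckts[current]["cards"].append(tokens)
        else:
            top.append((tokens[0], tokens))

    cards: List[Tuple[str, str, str, float]] = []

    def emit(tokens: List[str], node_map, prefix: str) -> None:
        name = tokens[0]
        kind = name[0].upper()
        if kind in ("R", "C"):
            a = node_map.get(tokens[1], prefix + tokens[1])
            b = node_map.get(tokens[2], prefix + tokens[2])
            cards.append((kind, a, b, _parse_value(tokens[3])))
        elif kind == "X":
            sub = subckts[tokens[-1]]
            inner_map = dict(zip(sub["ports"], (
                node_map.get(t, prefix + t) for t in tokens[1:-1]
            )))
            for inner in sub["cards"]:
                emit(inner, inner_map, prefix + name + ".")
        else:
            raise ValueError(f"unsupported card {name!r}")

    ground_map = {"0": "0"}
    for _, tokens in top:
        emit(tokens, ground_map, "")
    return cards


def evaluate_netlist(text: str, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """AC analysis of an R/C one-port netlist by modified nodal analysis.

    A unit current is injected into node ``in``; the node voltage is the
    input impedance.  Supports R and C cards and nested ``.subckt`` blocks.
    """
    cards = _flatten_netlist(text)
    nodes = sorted({n for _, a, b, _ in cards for n in (a, b)} - {"0"})
    if "in" not in nodes:
        raise ValueError("netlist must contain a node named 'in'")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    g = np.zeros((n, n))
    cmat = np.zeros((n, n))
    for kind, a, b, value in cards:
        mat = g if kind == "R" else cmat
        stamp = 1.0 / value if kind == "R" else value
        ia = index.get(a, -1)
        ib = index.get(b, -1)
        if ia >= 0:
            mat[ia, ia] += stamp
        if ib >= 0:
            mat[ib, ib] += stamp
        if ia >= 0 and ib >= 0:
            mat[ia, ib] -= stamp
            mat[ib, ia] -= stamp
    rhs = np.zeros(n, dtype=complex)
    rhs[index["in"]] = 1.0
    freqs = grid.frequencies
    z = np.empty(freqs.size, dtype=complex)
    for i, w in enumerate(2.0 * np.pi * freqs):
        z[i] = np.linalg.solve(g + 1j * w * cmat, rhs)[index["in"]]
    return ImpedanceSpectrum(freqs, z)
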