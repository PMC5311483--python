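"""Minimum-folding-energy backends for 35-nt windows.

The default backend is a simplified nearest-neighbor stacking model: a
dynamic program over canonical pairs (GC, AU, GU; T read as U) in which
helix energy comes from stacked-pair terms and closing a hairpin pays a
loop-size penalty. It is deliberately lightweight; any engine mapping a
35-nt string to a free energy (kcal/mol, <= 0) satisfies the backend
contract, and a ViennaRNA ``RNAfold`` subprocess backend is provided for
higher fidelity when the tool is on PATH.
"""

from __future__ import annotations

import math
import shutil
import subprocess

import numpy as np

WINDOW_LEN = 35

_PAIR_STRENGTH = {
    ("G", "C"): 1.7, ("C", "G"): 1.7,
    ("A", "T"): 0.9, ("T", "A"): 0.9,
    ("G", "T"): 0.5, ("T", "G"): 0.5,
}
_MIN_LOOP = 3
_HELIX_INIT = 1.0  # penalty for opening a helix (kcal/mol)


def _loop_penalty(size: int) -> float:
    return 4.5 + 1.0 * math.log(size / _MIN_LOOP)


class NearestNeighborBackend:
    """Simplified nearest-neighbor stacking DP (bundled default)."""

    name = "nearest-neighbor-stacking"

    def dg(self, seq: str) -> float:
        s = seq.upper().replace("U", "T")
        n = len(s)
        BIG = 1e9

        def pair(i: int, j: int) -> float | None:
            return _PAIR_STRENGTH.get((s[i], s[j]))

        # V[i][j]: best energy of i..j given (i, j) paired; W[i][j]: best of i..j
        V = np.full((n, n), BIG)
        W = np.zeros((n, n))
        for span in range(_MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                if pair(i, j) is not None:
                    best = _loop_penalty(j - i - 1)  # hairpin closure
                    if pair(i + 1, j - 1) is not None and V[i + 1][j - 1] < BIG / 2:
                        st = -(_PAIR_STRENGTH[(s[i], s[j])]
                               + _PAIR_STRENGTH[(s[i + 1], s[j - 1])])
                        best = min(best, V[i + 1][j - 1] + st)
                    if j - i - 1 > 2 * _MIN_LOOP:
                        best = min(best, W[i + 1][j - 1] + _HELIX_INIT)
                    V[i][j] = best
                w = min(W[i + 1][j], W[i][j - 1])
                for k in range(i + _MIN_LOOP + 1, j + 1):
                    if V[i][k] < BIG / 2:
                        rest = W[k + 1][j] if k + 1 <= j else 0.0
                        w = min(w, V[i][k] + rest)
                W[i][j] = w
        return float(min(0.0, W[0][n - 1]))


class ViennaRNABackend:
    """Optional backend shelling out to ``RNAfold --noPS``."""

    name = "viennarna-rnafold"

    def __init__(self) -> None:
        if shutil.which("RNAfold") is None:
            raise RuntimeError("RNAfold not found on PATH")

    def dg(self, seq: str) -> float:
        rna = seq.upper().replace("T", "U")
        proc = subprocess.run(
            ["RNAfold", "--noPS"], input=rna + "\n", capture_output=True,
            text=True, check=True,
        )
        last = proc.stdout.strip().splitlines()[-1]
        energy = last[last.rfind("(") + 1 : last.rfind(")")]
        return float(energy)


_DEFAULT_BACKEND = NearestNeighborBackend()


def fold_energy_window(sequence: str, backend=None) -> float:
    """Minimum folding energy (kcal/mol) of a 35-nt window; always <= 0.

    Structure propensity is reported downstream as -dG. Transcripts whose
    5'UTR is shorter than 35 nt must be excluded by the caller before this
    point.
    """
    if len(sequence) != WINDOW_LEN:
        raise ValueError(f"window must be exactly {WINDOW_LEN} nt, got {len(sequence)}")
    backend = backend or _DEFAULT_BACKEND
    try:
        dg = backend.dg(sequence)
    except Exception as exc:
        raise RuntimeError(
            f"folding backend {getattr(backend, 'name', backend)!r} failed: {exc}"
        ) from exc
    return min(0.0, float(dg))
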