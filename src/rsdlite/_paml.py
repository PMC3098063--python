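"""Loader for amino-acid exchangeability tables in the classic dat layout:
19 lower-triangular rows of exchangeabilities followed by a line of 20
stationary frequencies, residues ordered ARNDCQEGHILKMFPSTWYV."""

from __future__ import annotations

from importlib import resources

import numpy as np

from .seqio import AMINO_ACIDS

N_AA = len(AMINO_ACIDS)


def load_dat(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (symmetric 20x20 exchangeability matrix, stationary frequencies)."""
    text = resources.files("rsdlite.data").joinpath(f"{name}.dat").read_text()
    values = [float(x) for x in text.split()]
    n_tri = N_AA * (N_AA - 1) // 2
    if len(values) != n_tri + N_AA:
        raise ValueError(f"{name}.dat: expected {n_tri + N_AA} numbers, got {len(values)}")
    S = np.zeros((N_AA, N_AA))
    k = 0
    for i in range(1, N_AA):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    pi = np.asarray(values[k:], dtype=float)
    pi = pi / pi.sum()
    return S, pi
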