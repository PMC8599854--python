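"""Regenerate the packaged synthetic 30-signature reference matrix.

The matrix is a synthetic stand-in for the public 30-signature catalog: 96
channels x 30 signatures, columns summing to 1. Four profiles are shaped to
match well-known mutational processes so that domain-facing defaults behave
sensibly (Signature 1: CpG C>T deamination; Signature 3: near-flat, as in
homologous-recombination deficiency; Signature 4: C>A-dominant, as in tobacco
smoke exposure; Signature 5: flat clock-like); the remainder are sparse
random profiles from a fixed seed. Deterministic: rerunning reproduces the
packaged file byte-for-byte.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ithseq.mutational_signatures import CHANNELS

OUT = Path(__file__).resolve().parents[1] / "src" / "ithseq" / "data" / "signatures_30_synthetic.tsv"


def build_matrix() -> pd.DataFrame:
    rng = np.random.default_rng(20211117)
    channels = list(CHANNELS)
    sub_of = np.array([c[2:5] for c in channels])
    mat = np.zeros((96, 30))
    for j in range(30):
        name = j + 1
        # sparse random baseline: a handful of preferred channels
        base = rng.gamma(0.3, 1.0, size=96)
        if name == 1:  # CpG C>T
            mask = (sub_of == "C>T") & np.array([c.endswith("G") for c in channels])
            base[mask] += 12.0
        elif name == 3:  # broad, weakly structured
            base = np.full(96, 1.0) + rng.gamma(1.0, 0.6, size=96)
        elif name == 4:  # C>A dominant (tobacco)
            base[sub_of == "C>A"] += rng.gamma(2.0, 2.0, size=16)
        elif name == 5:  # broad with mild T>C enrichment
            base = np.full(96, 0.6) + rng.gamma(1.0, 0.3, size=96)
            base[sub_of == "T>C"] += rng.gamma(2.0, 1.0, size=16)
        mat[:, j] = base / base.sum()
    return pd.DataFrame(mat, index=channels, columns=[f"Signature {i}" for i in range(1, 31)])


if __name__ == "__main__":
    df = build_matrix()
    OUT.parent.mkdir(parents=True, exist_ok=True)
    df.round(8).to_csv(OUT, sep="\t", float_format="%.8f")
    print(f"wrote {OUT} ({OUT.stat().st_size} bytes)")
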