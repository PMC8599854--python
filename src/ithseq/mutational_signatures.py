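"""Mutational-signature catalogs and refitting.

Somatic single-nucleotide variants are summarised as counts over the 96
pyrimidine-strand trinucleotide substitution channels (6 substitution
classes x 16 flanking contexts). A sample catalog is then re-expressed as a
nonnegative mixture of 30 reference signature profiles by forward-selection
nonnegative least squares, the refitting strategy popularised by
deconstructSigs-style tools: signatures are added greedily while they reduce
the squared reconstruction error, weights below a reporting cutoff are zeroed,
and the survivors are renormalised to the pre-cutoff mass.

The packaged reference matrix is a synthetic stand-in for the public
30-signature catalog (see ``data/signatures_30_synthetic.tsv``): profiles are
generated deterministically with domain-shaped anchors (signature 1 is
CpG C>T-dominant, signature 3 near-flat, signature 4 C>A-dominant as in
tobacco exposure, signature 5 flat). All fitting behaviour is defined
relative to this packaged matrix; a user-supplied 96 x N matrix may be
substituted anywhere a ``reference`` argument is accepted.

Channel order is fixed: substitution classes C>A, C>G, C>T, T>A, T>C, T>G in
that order, contexts alphabetical within each class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The 96 channels, e.g. "A[C>A]A", in the conventional 6x16 layout.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

DEFAULT_CUTOFF = 0.06
DEFAULT_TOL = 1e-3


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def tnc_to_channel(tnc: str) -> str | None:
    """Map a 'ACA>AAA'-style trinucleotide substitution to its channel.

    The string carries the reference triplet and the alternate triplet; only
    the middle base changes. Purine-reference substitutions are collapsed to
    the pyrimidine strand by reverse complementing both triplets. Returns
    ``None`` for malformed strings or non-SNV changes.
    """
    if not isinstance(tnc, str) or len(tnc) != 7 or tnc[3] != ">":
        return None
    ref3, alt3 = tnc[:3], tnc[4:]
    if any(b not in _BASES for b in ref3 + alt3):
        return None
    if ref3[0] != alt3[0] or ref3[2] != alt3[2] or ref3[1] == alt3[1]:
        return None
    if ref3[1] in "AG":  # collapse to pyrimidine strand
        ref3, alt3 = _revcomp(ref3), _revcomp(alt3)
    channel = f"{ref3[0]}[{ref3[1]}>{alt3[1]}]{ref3[2]}"
    return channel if channel in _CHANNEL_INDEX else None


def channel_to_tnc(channel: str) -> str:
    """Inverse of :func:`tnc_to_channel` (pyrimidine strand representative)."""
    five, mid, three = channel[0], channel[2:5], channel[6]
    ref, alt = mid.split(">")
    return f"{five}{ref}{three}>{five}{alt}{three}"


def load_reference(path=None) -> pd.DataFrame:
    """Load a 96 x N reference signature matrix (channels x signatures).

    Without ``path`` the packaged synthetic 30-signature matrix is used.
    Rows are reindexed to the canonical channel order; columns are kept as
    named in the file.
    """
    if path is None:
        src = resources.files("ithseq.data").joinpath("signatures_30_synthetic.tsv")
        with resources.as_file(src) as p:
            ref = pd.read_csv(p, sep="\t", index_col=0)
    else:
        ref = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS) - set(ref.index)
    if missing:
        raise ValueError(f"reference matrix missing {len(missing)} channels")
    ref = ref.loc[list(CHANNELS)]
    if (ref.values < 0).any():
        raise ValueError("reference matrix has negative entries")
    return ref / ref.sum(axis=0)


@dataclass
class Catalog96:
    """Counts over the 96 trinucleotide substitution channels."""

    counts: pd.Series  # indexed by CHANNELS, nonnegative integers
    n_dropped: int = 0  # SNVs without a usable trinucleotide context

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def empty(self) -> bool:
        return self.total == 0


@dataclass
class SignatureExposure:
    """Nonnegative signature weights for one catalog.

    ``weights`` holds the post-cutoff weights (entries below the cutoff are
    exactly 0); ``raw_weights`` the pre-cutoff NNLS solution. The
    reconstruction error is the squared L2 distance between the normalised
    catalog and its reconstruction from the pre-cutoff weights.
    """

    weights: pd.Series
    raw_weights: pd.Series
    reconstruction_error: float
    selected: list[str] = field(default_factory=list)

    @property
    def residual(self) -> float:
        return float(1.0 - self.weights.sum())


def build_catalog(variants: pd.DataFrame, compartment: str = "all") -> Catalog96:
    """Build a channel catalog from a variant table.

    Uses the ``tnc`` column; rows lacking a parseable context (or indels) are
    excluded and tallied in ``n_dropped``. ``compartment`` selects rows by the
    ``compartment`` column when present and not 'all' ('nontrunk' matches
    everything except 'trunk').
    """
    df = variants
    if compartment != "all" and "compartment" in df.columns:
        if compartment == "nontrunk":
            df = df[df["compartment"] != "trunk"]
        else:
            df = df[df["compartment"] == compartment]
    counts = np.zeros(96, dtype=int)
    dropped = 0
    is_snv = (df["ref"].astype(str).str.len() == 1) & (df["alt"].astype(str).str.len() == 1)
    for tnc in df.loc[is_snv, "tnc"]:
        ch = tnc_to_channel(tnc) if isinstance(tnc, str) else None
        if ch is None:
            dropped += 1
        else:
            counts[_CHANNEL_INDEX[ch]] += 1
    dropped += int((~is_snv).sum())
    return Catalog96(pd.Series(counts, index=list(CHANNELS)), n_dropped=dropped)


def fit_signatures(
    catalog: Catalog96 | pd.Series | np.ndarray,
    reference: pd.DataFrame | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    tol: float = DEFAULT_TOL,
) -> SignatureExposure:
    """Refit a catalog against the reference signatures.

    Forward selection: at each step the signature whose inclusion most
    reduces the error of the NNLS fit to the normalised catalog is added;
    selection stops when the best improvement in the L2 reconstruction error
    (the Euclidean norm of the residual) falls below ``tol``.
    Weights below ``cutoff`` are then zeroed and the remaining weights are
    rescaled so their sum equals the pre-cutoff total. Fully deterministic.
    """
    if reference is None:
        reference = load_reference()
    v = np.asarray(catalog.counts if isinstance(catalog, Catalog96) else catalog, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot fit an empty catalog")
    v = v / total
    R = reference.values
    names = list(reference.columns)

    selected: list[int] = []
    best_w = np.zeros(0)
    err = float(np.sqrt(v @ v))  # L2 norm of the residual
    while len(selected) < len(names):
        best = None
        for j in range(len(names)):
            if j in selected:
                continue
            cols = selected + [j]
            w, rnorm = nnls(R[:, cols], v)
            if best is None or rnorm < best[1] - 1e-15:
                best = (j, rnorm, w)
        if best is None or err - best[1] < tol:
            break
        selected.append(best[0])
        err, best_w = best[1], best[2]
    raw = np.zeros(len(names))
    raw[selected] = best_w
    # keep weights on the [0,1] mixture scale
    if raw.sum() > 1.0:
        raw = raw / raw.sum()
    err = float(((v - R @ raw) ** 2).sum())
    pre_mass = raw.sum()
    w = raw.copy()
    w[w < cutoff] = 0.0
    if w.sum() > 0:
        w = w * (pre_mass / w.sum())
    raw_s = pd.Series(raw, index=names)
    return SignatureExposure(
        weights=pd.Series(w, index=names),
        raw_weights=raw_s,
        reconstruction_error=err,
        selected=[names[j] for j in selected],
    )


def trunk_nontrunk_contrast(
    exposures: dict[str, dict[str, pd.Series]],
    top_k: int = 5,
    test_signature: str | None = None,
) -> dict:
    """Contrast trunk vs nontrunk signature exposures across tumors.

    ``exposures`` maps tumor -> {'trunk': weights, 'nontrunk': weights}.
    Per compartment, exposures are pooled (summed) across tumors, signatures
    ranked by pooled weight, the top ``top_k`` kept and renormalised, giving
    each signature's share of the top-k mass. If ``test_signature`` is given,
    a two-sided paired Wilcoxon signed-rank test compares per-tumor shares of
    that signature between compartments over tumors where both compartments
    are available (missing compartments excluded pairwise).
    """
    out: dict = {"excluded_tumors": []}
    pooled = {}
    for comp in ("trunk", "nontrunk"):
        vecs = [e[comp] for e in exposures.values() if comp in e and e[comp].sum() > 0]
        pooled[comp] = sum(vecs) if vecs else pd.Series(dtype=float)
    for comp, pool in pooled.items():
        nz = pool[pool > 0].sort_values(ascending=False)
        k = min(top_k, len(nz))
        top = nz.iloc[:k]
        out[f"{comp}_top{top_k}_share"] = top / top.sum() if top.sum() > 0 else top
        out[f"{comp}_flagged_fewer_than_k"] = len(nz) < top_k
    if test_signature is not None:
        a, b = [], []
        for tumor, e in exposures.items():
            ok = all(c in e and e[c].sum() > 0 for c in ("trunk", "nontrunk"))
            if not ok:
                out["excluded_tumors"].append(tumor)
                continue
            shares = []
            for comp in ("trunk", "nontrunk"):
                top = pooled[comp][pooled[comp] > 0].sort_values(ascending=False).iloc[:top_k]
                mass = e[comp].reindex(top.index).fillna(0.0)
                shares.append(
                    float(mass.get(test_signature, 0.0) / mass.sum()) if mass.sum() > 0 else 0.0
                )
            a.append(shares[0])
            b.append(shares[1])
        diffs = np.asarray(a) - np.asarray(b)
        if len(diffs) < 1 or np.allclose(diffs, 0):
            out["p_value"] = 1.0
        else:
            out["p_value"] = float(stats.wilcoxon(a, b).pvalue)
        out["per_tumor_trunk_share"] = a
        out["per_tumor_nontrunk_share"] = b
    return out
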