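"""SBS96 spectra and constrained refitting of the seven-signature prostate panel.

The package works with the consensus panel SBS1, SBS2, SBS3, SBS5, SBS13,
SBS18 and SBS92, grouped for reporting into aging (SBS1/SBS5), APOBEC
(SBS2/SBS13), ROS (SBS18) and HRD (SBS3). Refitting is non-negative least
squares on the normalized spectrum followed by renormalization of the
weights to sum one.

The bundled reference table (``data/signature_profiles_synthetic.tsv``) is a
self-authored stylized stand-in: each signature is given its field-known
dominant context block (e.g. SBS1 as C>T at CpG, SBS2/13 as C>T / C>G at
TpC, SBS18 as C>A) on top of a flat background. It is synthetic, not the
COSMIC catalogue, and is only a default — any 96 x k column-stochastic
matrix can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .sbs96 import N_CHANNELS, channel_index, channel_labels, spectrum_from_channels

SIGNATURE_NAMES = ("SBS1", "SBS2", "SBS3", "SBS5", "SBS13", "SBS18", "SBS92")

#: Reporting groups used for per-sample presence calls.
SIGNATURE_GROUPS = {
    "aging": ("SBS1", "SBS5"),
    "APOBEC": ("SBS2", "SBS13"),
    "ROS": ("SBS18",),
    "HRD": ("SBS3",),
}


@dataclass
class ExposureVector:
    """Fitted signature weights for one spectrum."""

    weights: pd.Series
    residual: float
    n_mutations: int

    def __getitem__(self, name: str) -> float:
        return float(self.weights[name])


def load_reference_signatures() -> pd.DataFrame:
    """The bundled stylized 96 x 7 profile table (columns sum to 1)."""
    ref = resources.files("clonmosaic.data").joinpath("signature_profiles_synthetic.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def build_spectrum(variants: pd.DataFrame) -> np.ndarray:
    """SBS96 count vector from a variant table.

    Expects columns ``context`` (reference trinucleotide), ``ref`` and
    ``alt``; rows whose ref/alt are not single bases are rejected upstream.
    """
    if len(variants) == 0:
        return np.zeros(N_CHANNELS)
    idx = [
        channel_index(c, a)
        for c, a in zip(variants["context"].to_numpy(), variants["alt"].to_numpy())
    ]
    return spectrum_from_channels(np.asarray(idx))


def refit_exposures(spectrum: np.ndarray, signature_matrix: pd.DataFrame | np.ndarray) -> ExposureVector:
    """Non-negative least-squares refit of a spectrum onto signature profiles.

    Minimizes ``|| s/sum(s) - M w ||_2`` subject to ``w >= 0``, then
    renormalizes ``w`` to sum one. Deterministic.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    total = spectrum.sum()
    if total <= 0:
        raise ValueError("empty spectrum: no mutations to refit")
    if isinstance(signature_matrix, pd.DataFrame):
        names = list(signature_matrix.columns)
        M = signature_matrix.to_numpy(dtype=float)
    else:
        M = np.asarray(signature_matrix, dtype=float)
        names = [f"S{i+1}" for i in range(M.shape[1])]
    if M.shape[0] != spectrum.shape[0]:
        raise ValueError("signature matrix row count must match spectrum length")
    target = spectrum / total
    w, rnorm = nnls(M, target)
    s = w.sum()
    if s > 0:
        w = w / s
    return ExposureVector(
        weights=pd.Series(w, index=names),
        residual=float(rnorm),
        n_mutations=int(round(total)),
    )


def signature_presence(exposure: ExposureVector, min_weight: float = 0.05) -> dict[str, bool]:
    """Per-group presence calls: present iff any member weight >= min_weight."""
    out = {}
    for group, members in SIGNATURE_GROUPS.items():
        out[group] = any(
            m in exposure.weights.index and exposure.weights[m] >= min_weight
            for m in members
        )
    return out


def refit_samples(
    variants: pd.DataFrame,
    signature_matrix: pd.DataFrame | None = None,
    min_weight: float = 0.05,
    by: str = "sample_id",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spectra, exposures and presence tables per sample (or per any grouping).

    Only single-base substitutions with a context are used; a group with an
    empty spectrum is skipped. ``by`` may be a column name or list of names,
    so refitting per mutation-sharing class is the same call.
    """
    sig = load_reference_signatures() if signature_matrix is None else signature_matrix
    sbs = variants[
        (variants.get("variant_type", "SBS") == "SBS")
        & (variants["alt_count"] > 0)
        & (variants["context"].astype(str).str.len() == 3)
    ]
    labels = channel_labels()
    spectra, exposures, presence = {}, {}, {}
    for key, grp in sbs.groupby(by, sort=True):
        spec = build_spectrum(grp)
        if spec.sum() == 0:
            continue
        exp = refit_exposures(spec, sig)
        spectra[key] = spec
        exposures[key] = exp.weights
        presence[key] = signature_presence(exp, min_weight=min_weight)
    spectra_df = pd.DataFrame.from_dict(spectra, orient="index", columns=labels)
    exposures_df = pd.DataFrame.from_dict(exposures, orient="index")
    presence_df = pd.DataFrame.from_dict(presence, orient="index")
    return spectra_df, exposures_df, presence_df
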