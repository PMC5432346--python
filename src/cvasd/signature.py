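"""Gene-signature construction and nominal-hazard-ratio (nHR) scoring.

A signature is built from single-gene Cox interaction screens: genes are
ranked by the Wald p-value of their treatment x expression interaction, the
top ``g`` fits are retained, and a patient is scored by the nominal hazard
ratio

    nHR = exp(r * lambda_bar + sum_j (x_j * b_j + r * x_j * i_j))

over the ``g`` signature genes, where ``lambda_bar`` averages the treatment
main effect over the ``g`` single-gene fits. Patients with nHR strictly
below the threshold ``R`` are classified as treatment-sensitive
(radiosensitive): their modeled hazard under treatment is much lower than
the untreated baseline. The score is evaluated at ``r = 1`` by default —
the counterfactual "if treated" hazard ratio — regardless of the patient's
actual assignment, since the classification asks who would benefit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataValidationError
from .survival import GeneInteractionFit

__all__ = [
    "GeneInteractionFit",
    "SensitivityCall",
    "SignatureModel",
    "build_signature",
    "classify",
    "compute_nhr",
    "rank_genes",
]


def rank_genes(fits: list[GeneInteractionFit]) -> list[GeneInteractionFit]:
    """Order screen fits by interaction significance.

    Ascending interaction p-value; ties broken by larger |i_hat|, then by
    gene id, so the ranking is deterministic across platforms. Flagged fits
    carry p = 1 and sink to the bottom.
    """
    if not fits:
        raise DataValidationError("rank_genes: empty fit list")
    if all(f.p_interaction >= 1.0 for f in fits):
        warnings.warn(
            "all interaction fits flagged or uninformative (p = 1); "
            "ranking falls back to gene-id order",
            UserWarning,
            stacklevel=2,
        )
    return sorted(
        fits, key=lambda f: (f.p_interaction, -abs(f.i_hat), str(f.gene_id))
    )


@dataclass
class SignatureModel:
    """Top-g interaction fits plus the nHR threshold; scores any patient.

    ``lambda_bar`` is the treatment main effect averaged over the g
    single-gene models (a per-gene sum would scale with g).
    """

    fits: list[GeneInteractionFit]
    lambda_bar: float
    threshold_R: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.fits) < 1:
            raise ConfigurationError("signature needs at least one gene")
        if not self.threshold_R > 0:
            raise ConfigurationError("threshold_R must be positive")

    @property
    def g(self) -> int:
        return len(self.fits)

    @property
    def gene_ids(self) -> list:
        return [f.gene_id for f in self.fits]

    @property
    def b(self) -> np.ndarray:
        return np.array([f.b_hat for f in self.fits])

    @property
    def i(self) -> np.ndarray:
        return np.array([f.i_hat for f in self.fits])

    # -- serialization (TSV with a # header block) ---------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# g\t{self.g}\n")
            fh.write(f"# threshold_R\t{self.threshold_R!r}\n")
            fh.write(f"# lambda_bar\t{self.lambda_bar!r}\n")
            fh.write(
                "gene_id\tlambda_hat\tb_hat\ti_hat\tse_lambda\tse_b\tse_i"
                "\tp_interaction\tconverged\n"
            )
            for f in self.fits:
                fh.write(
                    f"{f.gene_id}\t{f.lambda_hat!r}\t{f.b_hat!r}\t{f.i_hat!r}"
                    f"\t{f.se_lambda!r}\t{f.se_b!r}\t{f.se_i!r}"
                    f"\t{f.p_interaction!r}\t{int(f.converged)}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "SignatureModel":
        header = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# "):
                    key, val = line[2:].split("\t")
                    header[key] = val
                elif line and not line.startswith("gene_id"):
                    rows.append(line.split("\t"))
        fits = [
            GeneInteractionFit(
                gene_id=r[0],
                lambda_hat=float(r[1]),
                b_hat=float(r[2]),
                i_hat=float(r[3]),
                se_lambda=float(r[4]),
                se_b=float(r[5]),
                se_i=float(r[6]),
                p_interaction=float(r[7]),
                converged=bool(int(r[8])),
            )
            for r in rows
        ]
        return cls(
            fits=fits,
            lambda_bar=float(header["lambda_bar"]),
            threshold_R=float(header["threshold_R"]),
        )


def build_signature(fits: list[GeneInteractionFit], g: int,
                    threshold_R: float, **meta) -> SignatureModel:
    """Take the top ``g`` genes after ranking and average their treatment effects."""
    if g < 1:
        raise ConfigurationError("g must be >= 1")
    if g > len(fits):
        raise ConfigurationError(
            f"g={g} exceeds the {len(fits)} available gene fits"
        )
    ranked = rank_genes(fits)
    top = ranked[:g]
    lambda_bar = float(np.mean([f.lambda_hat for f in top]))
    return SignatureModel(
        fits=top, lambda_bar=lambda_bar, threshold_R=threshold_R, meta=meta
    )


def _expression_vector(model: SignatureModel, x) -> np.ndarray:
    if isinstance(x, pd.Series):
        missing = [gid for gid in model.gene_ids if gid not in x.index]
        if missing:
            raise DataValidationError(
                f"expression value missing for signature gene(s): {missing}"
            )
        return x.loc[model.gene_ids].to_numpy(dtype=float)
    if isinstance(x, dict):
        missing = [gid for gid in model.gene_ids if gid not in x]
        if missing:
            raise DataValidationError(
                f"expression value missing for signature gene(s): {missing}"
            )
        return np.array([float(x[gid]) for gid in model.gene_ids])
    xv = np.asarray(x, dtype=float)
    if xv.shape != (model.g,):
        raise DataValidationError(
            f"expression vector has shape {xv.shape}, expected ({model.g},)"
        )
    return xv


def log_nhr(model: SignatureModel, x, r: int = 1) -> float:
    """log nHR = r*lambda_bar + sum_j (x_j b_j + r x_j i_j); overflow-safe."""
    xv = _expression_vector(model, x)
    return float(r * model.lambda_bar + xv @ (model.b + r * model.i))


def compute_nhr(model: SignatureModel, x, r: int = 1) -> float:
    """Nominal hazard ratio for one patient.

    ``x`` maps signature gene ids to standardized expression (Series/dict),
    or is an array already ordered as ``model.gene_ids``. ``r`` defaults to
    1: the score is the modeled hazard ratio the patient would have under
    treatment, relative to an untreated patient at mean expression.
    """
    return float(np.exp(np.clip(log_nhr(model, x, r=r), -700.0, 700.0)))


@dataclass
class SensitivityCall:
    patient_id: object
    nhr: float
    sensitive: bool


def classify(model: SignatureModel, x, r: int = 1,
             patient_id=None) -> SensitivityCall:
    """Classify a patient as treatment-sensitive when nHR < R (strict)."""
    nhr = compute_nhr(model, x, r=r)
    return SensitivityCall(
        patient_id=patient_id, nhr=nhr, sensitive=bool(nhr < model.threshold_R)
    )
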