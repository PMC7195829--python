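"""Per-protein feature extraction: the three families and their 167-D assembly.

Families, in fixed order:

1. **Domain flags** (63 values). For catalog domain ``D_i`` and a protein's
   annotated domain set ``A``, the score is ``X_i = 0`` if ``D_i`` is in
   ``A`` and ``1`` otherwise (the published encoding; ``polarity="presence"``
   inverts it, which tree ensembles are indifferent to).
2. **Physicochemical means** (24 values). For each amino-acid-index property,
   the mean index value over the sequence, ``PP = (1/L) * sum_i AAIndex_i``.
   Unknown residues (``X``) are skipped and ``L`` reduced accordingly.
3. **PSSM grey-model descriptor** (80 values). The L x 20 log-odds matrix is
   squashed elementwise through the logistic function ``1 / (1 + exp(-E))``
   (yielding the strictly positive series a grey model requires), then each
   of the 20 columns contributes its mean plus the three coefficients of a
   second-order grey model GM(2,1) fitted to it: 20 + 3 * 20 = 80 values.

The GM(2,1) fit for a positive series x0(1..L) builds the cumulative series
x1(k) = sum_{i<=k} x0(i), the first difference a(k) = x0(k) - x0(k-1), and
the mean sequence z1(k) = (x1(k) + x1(k-1)) / 2, and solves the least-squares
system with rows B(k) = [-x0(k), -z1(k), 1] and target Y(k) = a(k) for
k = 2..L. The minimum-norm solution is used, so degenerate (e.g. constant)
columns yield well-defined coefficients instead of failing.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import AA_ORDER, AAIndexTable, DomainCatalog, PSSM, ProteinRecord

#: Minimum sequence length for the PSSM descriptor (GM(2,1) needs >= 3
#: difference equations).
MIN_PSSM_LENGTH = 4

PSSM_MEAN_NAMES = tuple(f"pssm_mean_{j + 1}" for j in range(20))
PSSM_GM_NAMES = tuple(
    f"gm_{coef}_{j + 1}" for j in range(20) for coef in ("a1", "a2", "b")
)
PSSM_FEATURE_NAMES = PSSM_MEAN_NAMES + PSSM_GM_NAMES


@dataclasses.dataclass(frozen=True)
class GreyModelParams:
    """Coefficients of a GM(2,1) grey model fitted to one PSSM column."""

    a1: float
    a2: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.b])


def feature_names(catalog: DomainCatalog, table: AAIndexTable) -> list[str]:
    """The fixed global feature order: domains, properties, PSSM descriptor."""
    return list(catalog.accessions) + list(table.properties) + list(PSSM_FEATURE_NAMES)


def domain_features(
    protein_id: str,
    annotations: Mapping[str, set[str]],
    catalog: DomainCatalog,
    polarity: str = "as_printed",
) -> np.ndarray:
    """Binary domain flags in catalog order.

    ``as_printed`` emits 0 for a present domain and 1 for an absent one;
    ``presence`` emits the complement. A protein missing from the annotation
    map has the empty domain set.
    """
    if polarity not in ("as_printed", "presence"):
        raise ValueError(f"unknown polarity {polarity!r}")
    annotated = annotations.get(protein_id, set())
    present = np.array([acc in annotated for acc in catalog.accessions], dtype=float)
    return present if polarity == "presence" else 1.0 - present


def physchem_features(sequence: str, table: AAIndexTable) -> np.ndarray:
    """Mean amino-acid-index value per property; ``X`` residues are skipped."""
    counted = [r for r in sequence if r != "X"]
    if not counted:
        raise ValueError("sequence consists only of unknown residues ('X'); "
                         "physicochemical means are undefined")
    counts = pd.Series(counted).value_counts()
    weights = np.zeros(20)
    for j, res in enumerate(AA_ORDER):
        weights[j] = counts.get(res, 0)
    weights /= weights.sum()
    # property means = (24 x 20 value matrix) @ residue frequencies
    values = table.values[list(AA_ORDER)].to_numpy(dtype=float)
    return values @ weights


def standardize_pssm(pssm: PSSM) -> np.ndarray:
    """Logistic squashing of the log-odds scores into (0, 1)."""
    if pssm.length < MIN_PSSM_LENGTH:
        raise ValueError(
            f"protein {pssm.protein_id!r} has length {pssm.length}; the PSSM "
            f"descriptor requires at least {MIN_PSSM_LENGTH} residues"
        )
    return expit(pssm.scores.astype(float))


def fit_gm21(column: Sequence[float]) -> GreyModelParams:
    """Least-squares GM(2,1) coefficients for one positive series."""
    x0 = np.asarray(column, dtype=float)
    if x0.ndim != 1 or x0.size < MIN_PSSM_LENGTH:
        raise ValueError(f"GM(2,1) needs a 1-D series of length >= {MIN_PSSM_LENGTH}")
    if np.any(x0 <= 0):
        raise ValueError("GM(2,1) requires a strictly positive series")
    x1 = np.cumsum(x0)
    alpha = x0[1:] - x0[:-1]            # first difference, k = 2..L
    z1 = 0.5 * (x1[1:] + x1[:-1])       # consecutive-mean of the cumulative series
    B = np.column_stack([-x0[1:], -z1, np.ones_like(z1)])
    params, *_ = np.linalg.lstsq(B, alpha, rcond=None)
    return GreyModelParams(a1=float(params[0]), a2=float(params[1]), b=float(params[2]))


def pssm_features(pssm: PSSM) -> np.ndarray:
    """The 80-D PSSM descriptor: 20 column means + GM(2,1) triple per column."""
    std = standardize_pssm(pssm)
    means = std.mean(axis=0)
    gm = np.concatenate([fit_gm21(std[:, j]).as_array() for j in range(20)])
    return np.concatenate([means, gm])


def extract_features(
    protein: ProteinRecord,
    annotations: Mapping[str, set[str]],
    pssm: PSSM,
    catalog: DomainCatalog,
    table: AAIndexTable,
    polarity: str = "as_printed",
) -> pd.Series:
    """Assemble the full fixed-order feature vector for one protein."""
    if pssm.length != protein.length:
        raise ValueError(
            f"protein {protein.id!r}: PSSM has {pssm.length} rows but the "
            f"sequence has length {protein.length}"
        )
    values = np.concatenate(
        [
            domain_features(protein.id, annotations, catalog, polarity=polarity),
            physchem_features(protein.sequence, table),
            pssm_features(pssm),
        ]
    )
    vector = pd.Series(values, index=feature_names(catalog, table), name=protein.id)
    if not np.all(np.isfinite(vector.to_numpy())):
        raise ValueError(f"protein {protein.id!r}: non-finite feature value")
    return vector


def extract_feature_table(
    records: Sequence[ProteinRecord],
    annotations: Mapping[str, set[str]],
    pssms: Mapping[str, PSSM],
    catalog: DomainCatalog,
    table: AAIndexTable,
    polarity: str = "as_printed",
) -> pd.DataFrame:
    """Feature matrix for a protein collection (rows = proteins, fixed column order)."""
    rows = [
        extract_features(rec, annotations, pssms[rec.id], catalog, table, polarity=polarity)
        for rec in records
    ]
    return pd.DataFrame(rows)
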