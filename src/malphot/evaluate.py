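"""Analysis views: per-class error, solvatochromic trends, structure map.

These reproduce the standard post-hoc checks for a solvent-aware wavelength
regressor: how prediction error distributes over substitution classes
(under-represented classes are expected to fare worse), whether the
predicted wavelength rises monotonically with solvent dielectric constant
the way the measured spectra do, and a pairwise Tanimoto-distance matrix
over unique structures ready for embedding (e.g. t-SNE) by any standard
tool.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from malphot.dataset_io import (
    PhotophysicsRecord,
    SubstitutionClass,
    canonical_smiles,
)
from malphot.featurize import fingerprint_smiles, tanimoto
from malphot.model import TrainedSpectralModel, predict_wavelength


@dataclass
class ClassStats:
    n: int
    mean_abs_deviation: float  # nm
    max_deviation: float       # nm
    signed_bias: float         # mean(predicted - observed), nm


@dataclass
class ClassPerformance:
    """Residual summaries grouped by substitution class.

    Classes with zero evaluated records are absent, not reported as
    zero-error.
    """

    per_class: dict[SubstitutionClass, ClassStats]
    n_total: int

    def to_dict(self) -> dict:
        return {
            cls.value: vars(stats) for cls, stats in self.per_class.items()
        }


def class_performance(
    model: TrainedSpectralModel, records: list[PhotophysicsRecord]
) -> ClassPerformance:
    """Per-class residuals of model predictions against observed wavelengths."""
    target = model.config.target
    groups: dict[SubstitutionClass, list[float]] = {}
    n_total = 0
    for rec in records:
        obs = rec.lambda_em if target == "emission" else rec.lambda_abs
        if obs is None:
            continue
        pred = predict_wavelength(model, rec.smiles, rec.dielectric)
        groups.setdefault(rec.substitution_class, []).append(pred - obs)
        n_total += 1
    per_class = {
        cls: ClassStats(
            n=len(res),
            mean_abs_deviation=float(np.mean(np.abs(res))),
            max_deviation=float(np.max(np.abs(res))),
            signed_bias=float(np.mean(res)),
        )
        for cls, res in groups.items()
    }
    return ClassPerformance(per_class=per_class, n_total=n_total)


@dataclass
class TrendRow:
    smiles: str
    substitution_class: SubstitutionClass
    eps_min: float
    eps_max: float
    predicted_delta: float          # nm over [eps_min, eps_max]
    observed_delta: float | None    # nm, when measured in >= 2 solvents
    monotonic_fraction: float       # fraction of consecutive eps-ordered pairs
                                    # with nondecreasing predicted wavelength


@dataclass
class TrendReport:
    rows: list[TrendRow]
    skipped: list[str] = field(default_factory=list)  # SMILES with < 2 solvents


def solvato_trend(
    model: TrainedSpectralModel, records: list[PhotophysicsRecord]
) -> TrendReport:
    """Per-molecule solvatochromic shift, predicted vs observed.

    Observed shifts use the two extreme-dielectric solvents available for
    the molecule; molecules measured in fewer than two solvents are skipped
    with notice.
    """
    target = model.config.target
    by_mol: dict[str, list[PhotophysicsRecord]] = {}
    for rec in records:
        by_mol.setdefault(canonical_smiles(rec.smiles), []).append(rec)

    rows: list[TrendRow] = []
    skipped: list[str] = []
    for smi, recs in by_mol.items():
        eps_sorted = sorted({r.dielectric for r in recs})
        if len(eps_sorted) < 2:
            skipped.append(smi)
            continue
        preds = [predict_wavelength(model, smi, e) for e in eps_sorted]
        steps = [b >= a - 1e-9 for a, b in zip(preds, preds[1:])]
        mono = sum(steps) / len(steps)

        def obs_at(eps: float) -> float | None:
            for r in recs:
                if r.dielectric == eps:
                    return r.lambda_em if target == "emission" else r.lambda_abs
            return None

        lo, hi = obs_at(eps_sorted[0]), obs_at(eps_sorted[-1])
        observed = (hi - lo) if (lo is not None and hi is not None) else None
        rows.append(
            TrendRow(
                smiles=smi,
                substitution_class=recs[0].substitution_class,
                eps_min=eps_sorted[0],
                eps_max=eps_sorted[-1],
                predicted_delta=preds[-1] - preds[0],
                observed_delta=observed,
                monotonic_fraction=mono,
            )
        )
    return TrendReport(rows=rows, skipped=skipped)


@dataclass
class SimilarityMatrix:
    """Pairwise Tanimoto distances (1 - similarity) over unique structures."""

    labels: list[str]  # canonical SMILES
    distances: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["smiles", *self.labels])
            for label, row in zip(self.labels, self.distances):
                writer.writerow([label, *(f"{v:.6f}" for v in row)])


def tanimoto_distance_matrix(
    records: list[PhotophysicsRecord] | list[str],
    radius: int = 5,
    n_bits: int = 1024,
) -> SimilarityMatrix:
    """Tanimoto distance matrix over deduplicated structures.

    Accepts records or raw SMILES.  Unparsable structures are excluded with
    notice (collected in the matrix labels only if they parse).  The export
    is intended as input to an external embedding tool.
    """
    smiles_in = [
        r.smiles if isinstance(r, PhotophysicsRecord) else r for r in records
    ]
    labels: list[str] = []
    seen: set[str] = set()
    for smi in smiles_in:
        try:
            canon = canonical_smiles(smi)
        except ValueError:
            continue  # unparsable structure excluded
        if canon not in seen:
            seen.add(canon)
            labels.append(canon)
    if len(labels) < 1:
        raise ValueError("no parsable structures")
    fps = [fingerprint_smiles(s, radius=radius, n_bits=n_bits) for s in labels]
    n = len(labels)
    dist = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - tanimoto(fps[i], fps[j])
            dist[i, j] = dist[j, i] = d
    return SimilarityMatrix(labels=labels, distances=dist)
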