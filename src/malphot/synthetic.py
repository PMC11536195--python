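"""Synthetic maleimide photophysics datasets with a known wavelength law.

The generator fabricates datasets with the statistical structure of the
curated literature set: four substitution classes (amino-, dithio-,
aminothio- and alkoxymaleimides) with class-specific base wavelengths,
small substituent increments, a monotone saturating solvatochromic shift
over the dielectric range of common solvents, amino-dominated class
proportions, several solvents per molecule, and Gaussian measurement
noise.  The paired ground-truth table makes every downstream stage
(loading, featurization, training, evaluation) testable against noise-free
values.  The law is a test harness, not a photophysics model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from malphot.dataset_io import (
    PhotophysicsRecord,
    SolventRegistry,
    SubstitutionClass,
    canonical_smiles,
    classify_substitution,
    write_dataset,
)

# -- fragment library --------------------------------------------------------
# SMILES fragments attach directly after the heteroatom written in the core
# template; ring-closure digits >= 2 avoid clashing with the core ring.
AMINE_FRAGMENTS = {
    "methyl": "C",
    "ethyl": "CC",
    "propyl": "CCC",
    "butyl": "CCCC",
    "isopropyl": "C(C)C",
    "isobutyl": "CC(C)C",
    "tert-butyl": "C(C)(C)C",
    "cyclopropyl": "C2CC2",
    "cyclopentyl": "C2CCCC2",
    "cyclohexyl": "C2CCCCC2",
    "allyl": "CC=C",
    "propargyl": "CC#C",
}
THIOL_FRAGMENTS = {
    "methyl": "C",
    "ethyl": "CC",
    "butyl": "CCCC",
    "phenyl": "c2ccccc2",
}
ALKOXY_FRAGMENTS = {
    "methyl": "C",
    "ethyl": "CC",
    "butyl": "CCCC",
}
CAP_FRAGMENTS = {  # imide-N substituent; "H" leaves the ring NH
    "H": "",
    "methyl": "C",
    "ethyl": "CC",
    "butyl": "CCCC",
    "phenyl": "c2ccccc2",
}

_CLASS_ARITY = {
    SubstitutionClass.AM: 1,
    SubstitutionClass.DTM: 2,
    SubstitutionClass.ATM: 2,
    SubstitutionClass.ALKOXY: 1,
}


def enumerate_smiles(
    cls: SubstitutionClass, cap: str, substituents: tuple[str, ...]
) -> str:
    """Build a canonical maleimide SMILES from named fragments.

    ``cap`` names the imide-N fragment; ``substituents`` name the alkene
    fragments (one for AM/alkoxy; thiol then amine for ATM; two thiols for
    DTM).  The result always classifies back to the requested class.
    """
    if cap not in CAP_FRAGMENTS:
        raise ValueError(f"unknown imide cap {cap!r}")
    if len(substituents) != _CLASS_ARITY.get(cls, -1):
        raise ValueError(
            f"{cls.value} takes {_CLASS_ARITY.get(cls)} substituent(s), "
            f"got {len(substituents)}"
        )
    cap_smi = CAP_FRAGMENTS[cap]
    n_part = f"N({cap_smi})" if cap_smi else "N"
    if cls is SubstitutionClass.AM:
        (amine,) = substituents
        body = f"O=C1{n_part}C(=O)C=C1N{AMINE_FRAGMENTS[amine]}"
    elif cls is SubstitutionClass.ALKOXY:
        (ether,) = substituents
        body = f"O=C1{n_part}C(=O)C=C1O{ALKOXY_FRAGMENTS[ether]}"
    elif cls is SubstitutionClass.DTM:
        t1, t2 = substituents
        body = f"O=C1{n_part}C(=O)C(S{THIOL_FRAGMENTS[t1]})=C1S{THIOL_FRAGMENTS[t2]}"
    elif cls is SubstitutionClass.ATM:
        thiol, amine = substituents
        body = (
            f"O=C1{n_part}C(=O)C(S{THIOL_FRAGMENTS[thiol]})"
            f"=C1N{AMINE_FRAGMENTS[amine]}"
        )
    else:
        raise ValueError(f"no template for class {cls.value}")
    smi = canonical_smiles(body)
    got = classify_substitution(smi)
    if got is not cls:
        raise RuntimeError(f"template produced {got.value}, wanted {cls.value}")
    return smi


# -- ground-truth wavelength law ---------------------------------------------

def _onsager(eps: float) -> float:
    return (eps - 1.0) / (eps + 2.0)


#: Substituent wavelength increments (nm), mean-zero within each library so
#: class means stay at the class anchors.
DEFAULT_SUBSTITUENT_SHIFTS = {
    "amine": {
        "methyl": -2.0, "ethyl": -1.0, "propyl": 0.0, "butyl": 1.0,
        "isopropyl": 0.0, "isobutyl": 1.0, "tert-butyl": 3.0,
        "cyclopropyl": -2.0, "cyclopentyl": 1.0, "cyclohexyl": 2.0,
        "allyl": -1.0, "propargyl": -2.0,
    },
    "thiol": {"methyl": -2.0, "ethyl": -1.0, "butyl": 1.0, "phenyl": 2.0},
    "ether": {"methyl": -1.0, "ethyl": 0.0, "butyl": 1.0},
}


@dataclass
class GroundTruthModel:
    """Noise-free synthetic wavelength law.

    lambda_abs(class, subs, eps) = base[class] + sum(substituent shifts)
                                   + amplitude[class] * g(eps)
    lambda_em = lambda_abs + stokes[class]

    g is an Onsager-style saturating response (eps-1)/(eps+2) rescaled so
    g(1) = 0 and g(37.5) = 1: monotone nondecreasing in eps and bounded,
    while still rising at high dielectric constant.  Default anchors put
    amino-maleimide absorption near 365 nm in hexane rising to ~385 nm for
    eps > 30 (a shift of ~18 nm across the solvent range), dithio
    absorption around 410 nm on average, the thio-for-amino increment near
    +30 nm, the amino-vs-alkoxy offset at +35 nm, and amino emission in
    the 450 nm region.
    """

    base: dict[SubstitutionClass, float] = field(
        default_factory=lambda: {
            SubstitutionClass.AM: 361.0,
            SubstitutionClass.DTM: 395.0,
            SubstitutionClass.ATM: 385.0,
            SubstitutionClass.ALKOXY: 326.0,
        }
    )
    amplitude: dict[SubstitutionClass, float] = field(
        default_factory=lambda: {
            SubstitutionClass.AM: 24.0,
            SubstitutionClass.DTM: 24.0,
            SubstitutionClass.ATM: 24.0,
            SubstitutionClass.ALKOXY: 20.0,
        }
    )
    stokes: dict[SubstitutionClass, float] = field(
        default_factory=lambda: {
            SubstitutionClass.AM: 82.0,
            SubstitutionClass.DTM: 62.0,
            SubstitutionClass.ATM: 72.0,
            SubstitutionClass.ALKOXY: 70.0,
        }
    )
    substituent_shifts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_SUBSTITUENT_SHIFTS.items()
        }
    )
    chloroform_anomaly: bool = False  # chloroform reads ~8 nm red of its eps
    chloroform_offset: float = 8.0

    def solvent_response(self, eps: float) -> float:
        """g(eps) in [0, 1]: 0 at eps = 1, 1 at eps = 37.5, monotone."""
        return _onsager(eps) / _onsager(37.5)

    def _shift_sum(self, cls: SubstitutionClass, subs: tuple[str, ...]) -> float:
        kinds = {
            SubstitutionClass.AM: ("amine",),
            SubstitutionClass.ALKOXY: ("ether",),
            SubstitutionClass.DTM: ("thiol", "thiol"),
            SubstitutionClass.ATM: ("thiol", "amine"),
        }[cls]
        return sum(
            self.substituent_shifts[kind][name]
            for kind, name in zip(kinds, subs)
        )

    def lambda_abs(
        self,
        cls: SubstitutionClass,
        subs: tuple[str, ...],
        eps: float,
        solvent_name: str = "",
    ) -> float:
        lam = (
            self.base[cls]
            + self._shift_sum(cls, subs)
            + self.amplitude[cls] * self.solvent_response(eps)
        )
        if self.chloroform_anomaly and solvent_name.strip().casefold() == "chloroform":
            lam += self.chloroform_offset
        return lam

    def lambda_em(
        self,
        cls: SubstitutionClass,
        subs: tuple[str, ...],
        eps: float,
        solvent_name: str = "",
    ) -> float:
        return self.lambda_abs(cls, subs, eps, solvent_name) + self.stokes[cls]


DEFAULT_SOLVENTS = (
    "hexane",
    "dioxane",
    "diethyl ether",
    "chloroform",
    "methanol",
    "acetonitrile",
)


@dataclass
class GeneratorConfig:
    """Sampling parameters for the synthetic dataset.

    Defaults emulate the curated literature set: 64 unique molecules,
    amino-dominated class proportions (66/13/10/11%), 2-6 solvents per
    molecule drawn from the six common solvents, and 5 nm measurement
    noise on each wavelength.
    """

    n_molecules: int = 64
    class_proportions: dict[SubstitutionClass, float] = field(
        default_factory=lambda: {
            SubstitutionClass.AM: 0.66,
            SubstitutionClass.DTM: 0.13,
            SubstitutionClass.ATM: 0.10,
            SubstitutionClass.ALKOXY: 0.11,
        }
    )
    solvents: tuple[str, ...] = DEFAULT_SOLVENTS
    solvents_per_molecule: tuple[int, int] = (2, 6)  # inclusive range
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if not self.solvents:
            raise ValueError("empty solvent set")


def _draw_substituents(
    rng: np.random.Generator, cls: SubstitutionClass
) -> tuple[str, ...]:
    amines = sorted(AMINE_FRAGMENTS)
    thiols = sorted(THIOL_FRAGMENTS)
    ethers = sorted(ALKOXY_FRAGMENTS)
    pick = lambda pool: pool[rng.integers(len(pool))]
    if cls is SubstitutionClass.AM:
        return (pick(amines),)
    if cls is SubstitutionClass.ALKOXY:
        return (pick(ethers),)
    if cls is SubstitutionClass.DTM:
        return (pick(thiols), pick(thiols))
    return (pick(thiols), pick(amines))  # ATM: thiol + amine


def generate_dataset(
    config: GeneratorConfig,
    truth: GroundTruthModel | None = None,
    registry: SolventRegistry | None = None,
) -> tuple[list[PhotophysicsRecord], dict[tuple[str, str], tuple[float, float]]]:
    """Draw a synthetic dataset plus its noise-free truth table.

    Returns ``(records, truth_table)`` where the table maps
    ``(canonical SMILES, solvent name) -> (lambda_abs, lambda_em)`` without
    noise.  Fully reproducible from ``config.seed``.
    """
    truth = truth or GroundTruthModel()
    registry = registry or SolventRegistry.default()
    rng = np.random.default_rng(config.seed)

    classes = sorted(config.class_proportions, key=lambda c: c.value)
    probs = np.array([config.class_proportions[c] for c in classes])
    caps = sorted(CAP_FRAGMENTS)

    molecules: list[tuple[str, SubstitutionClass, tuple[str, ...]]] = []
    seen: set[str] = set()
    attempts = 0
    while len(molecules) < config.n_molecules:
        attempts += 1
        if attempts > 200 * config.n_molecules:
            raise RuntimeError(
                "fragment library exhausted before reaching n_molecules"
            )
        cls = classes[rng.choice(len(classes), p=probs)]
        cap = caps[rng.integers(len(caps))]
        subs = _draw_substituents(rng, cls)
        smi = enumerate_smiles(cls, cap, subs)
        if smi in seen:
            continue
        seen.add(smi)
        molecules.append((smi, cls, subs))

    lo, hi = config.solvents_per_molecule
    records: list[PhotophysicsRecord] = []
    truth_table: dict[tuple[str, str], tuple[float, float]] = {}
    for smi, cls, subs in molecules:
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(config.solvents))
        chosen = rng.choice(len(config.solvents), size=k, replace=False)
        for idx in sorted(chosen):
            solvent = config.solvents[idx]
            eps = registry.lookup(solvent)
            abs_true = truth.lambda_abs(cls, subs, eps, solvent)
            em_true = truth.lambda_em(cls, subs, eps, solvent)
            truth_table[(smi, solvent)] = (abs_true, em_true)
            lam_abs = abs_true + rng.normal(0.0, config.noise_sigma)
            lam_em = em_true + rng.normal(0.0, config.noise_sigma)
            lam_em = max(lam_em, lam_abs + 5.0)  # emission stays red of absorption
            rec = PhotophysicsRecord(
                smiles=smi,
                solvent_name=solvent,
                dielectric=eps,
                lambda_abs=round(lam_abs, 2),
                lambda_em=round(lam_em, 2),
                substitution_class=cls,
                source=f"synthetic-seed{config.seed}",
            )
            rec.validate()
            records.append(rec)
    return records, truth_table


def write_synthetic_dataset(
    records: list[PhotophysicsRecord],
    truth_table: dict[tuple[str, str], tuple[float, float]],
    dataset_path: str | Path,
    truth_path: str | Path | None = None,
    seed: int | None = None,
) -> None:
    """Write the dataset CSV (loadable by load_dataset) and the truth table."""
    write_dataset(records, dataset_path)
    if seed is not None:
        text = Path(dataset_path).read_text()
        Path(dataset_path).write_text(
            f"# malphot synthetic dataset, generator seed={seed}\n" + text
        )
    if truth_path is not None:
        lines = ["smiles,solvent,lambda_abs_true_nm,lambda_em_true_nm"]
        for (smi, solvent), (ab, em) in truth_table.items():
            lines.append(f"{smi},{solvent},{ab:.4f},{em:.4f}")
        Path(truth_path).write_text("\n".join(lines) + "\n")


def all_enumerable_smiles() -> list[str]:
    """Every SMILES the fragment library can produce (deduplicated)."""
    out: set[str] = set()
    for cap in CAP_FRAGMENTS:
        for amine in AMINE_FRAGMENTS:
            out.add(enumerate_smiles(SubstitutionClass.AM, cap, (amine,)))
        for ether in ALKOXY_FRAGMENTS:
            out.add(enumerate_smiles(SubstitutionClass.ALKOXY, cap, (ether,)))
        for t1, t2 in itertools.product(THIOL_FRAGMENTS, repeat=2):
            out.add(enumerate_smiles(SubstitutionClass.DTM, cap, (t1, t2)))
        for t, a in itertools.product(THIOL_FRAGMENTS, AMINE_FRAGMENTS):
            out.add(enumerate_smiles(SubstitutionClass.ATM, cap, (t, a)))
    return sorted(out)
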