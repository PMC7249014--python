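"""Physicochemical and blood–brain-barrier triage of candidate compounds.

The filtering phase of the pipeline: each mined compound is parsed from
SMILES, profiled with oral-bioavailability descriptors, gated by the
Lipinski rule of five (with the TPSA and rotatable-bond extensions), banded
by Wildman–Crippen clogP, and scored for passive blood–brain-barrier (BBB)
permeation by a linear SVM over hashed circular (Morgan) fingerprints.

Descriptor conventions
----------------------
* HBD / HBA use Lipinski's original N/O counting: a donor is any nitrogen
  or oxygen bearing at least one hydrogen; an acceptor is any nitrogen or
  oxygen.  Toolkit donor/acceptor SMARTS definitions differ from this, so
  the counts are computed directly from the atom table.
* The molecular-weight bound is strict (< 500 Da); the other four bounds
  are inclusive.  Two or more violations predict poor oral absorption.
* clogP bands: negative values indicate aqueous-phase affinity (poor
  membrane permeation), values >= 5.0 indicate poor absorption from excess
  lipophilicity, and the band between is optimal.

Suitability requires all three gates: fewer than two rule violations, an
optimal clogP band, and a positive BBB decision.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

RDLogger.DisableLog("rdApp.*")  # parse errors are reported via exceptions

logger = logging.getLogger(__name__)


class TriageError(Exception):
    pass


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    name: str
    smiles: str

    def __post_init__(self) -> None:
        if not self.name:
            raise TriageError("compound name must be non-empty")


@dataclass(frozen=True)
class DescriptorSet:
    mw: float  # Da
    hbd: int
    hba: int
    tpsa: float  # Angstrom^2
    rotatable_bonds: int
    clogp: float


@dataclass(frozen=True)
class LipinskiRuleConfig:
    mw_max: float = 500.0  # strict <
    hbd_max: int = 5  # inclusive
    hba_max: int = 10
    tpsa_max: float = 140.0
    rotb_max: int = 10
    violation_fail_count: int = 2


@dataclass
class BBBModel:
    """Linear decision function over fingerprint bits: score = w.x + b."""

    weights: np.ndarray
    bias: float
    n_bits: int = 1024
    radius: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.n_bits,):
            raise TriageError(
                f"weight vector length {self.weights.shape} != n_bits {self.n_bits}"
            )
        if not (np.all(np.isfinite(self.weights)) and math.isfinite(self.bias)):
            raise TriageError("non-finite BBB model parameters")


@dataclass(frozen=True)
class TriageVerdict:
    name: str
    descriptors: DescriptorSet
    violations: int
    poor_oral: bool
    clogp_band: str  # aqueous | optimal | high
    bbb_score: float
    bbb_crossing: bool
    suitable: bool
    rank: int


# ---------------------------------------------------------------------------
# Structure handling and descriptors
# ---------------------------------------------------------------------------


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES into a sanitized molecule (aromaticity perceived,
    implicit hydrogens assigned). Raises on syntax or valence errors."""
    if not smiles:
        raise TriageError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise TriageError(f"unparseable SMILES {smiles!r}")
    return mol


def molecular_weight(mol: Chem.Mol) -> float:
    """Average molecular weight in Da, implicit hydrogens included."""
    return float(Descriptors.MolWt(mol))


def count_hbd(mol: Chem.Mol) -> int:
    """Lipinski donors: N or O atoms bearing >= 1 hydrogen."""
    return sum(
        1
        for a in mol.GetAtoms()
        if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() >= 1
    )


def count_hba(mol: Chem.Mol) -> int:
    """Lipinski acceptors: all N and O atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))


def tpsa(mol: Chem.Mol) -> float:
    """Topological polar surface area from Ertl fragment contributions."""
    return float(rdMolDescriptors.CalcTPSA(mol))


def rotatable_bonds(mol: Chem.Mol) -> int:
    """Non-ring single bonds between two non-terminal heavy atoms,
    excluding amide C-N bonds (strict definition)."""
    return int(
        rdMolDescriptors.CalcNumRotatableBonds(
            mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
        )
    )


def crippen_clogp(mol: Chem.Mol) -> float:
    """Wildman–Crippen atom-contribution logP."""
    return float(Crippen.MolLogP(mol))


def crippen_atom_contributions(mol: Chem.Mol) -> list[float]:
    """Per-atom Wildman–Crippen contributions on the explicit-H graph.

    Their sum equals :func:`crippen_clogp`; exposed so the additivity of
    the published table is directly checkable.
    """
    molh = Chem.AddHs(mol)
    return [c[0] for c in rdMolDescriptors._CalcCrippenContribs(molh)]


def compute_descriptors(mol: Chem.Mol) -> DescriptorSet:
    return DescriptorSet(
        mw=molecular_weight(mol),
        hbd=count_hbd(mol),
        hba=count_hba(mol),
        tpsa=tpsa(mol),
        rotatable_bonds=rotatable_bonds(mol),
        clogp=crippen_clogp(mol),
    )


def lipinski_violations(desc: DescriptorSet, config: LipinskiRuleConfig | None = None) -> int:
    cfg = config or LipinskiRuleConfig()
    return sum(
        (
            desc.mw >= cfg.mw_max,  # MW bound is strict "< 500"
            desc.hbd > cfg.hbd_max,
            desc.hba > cfg.hba_max,
            desc.tpsa > cfg.tpsa_max,
            desc.rotatable_bonds > cfg.rotb_max,
        )
    )


def clogp_band(clogp: float) -> str:
    """aqueous (< 0), optimal ([0, 5)), or high (>= 5)."""
    if not math.isfinite(clogp):
        raise TriageError(f"non-finite clogp {clogp!r}")
    if clogp < 0.0:
        return "aqueous"
    if clogp >= 5.0:
        return "high"
    return "optimal"


# ---------------------------------------------------------------------------
# Fingerprints and BBB permeability SVM
# ---------------------------------------------------------------------------


def fingerprint(mol: Chem.Mol, n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """Hashed circular (Morgan) fingerprint as a 0/1 vector."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.asarray(gen.GetFingerprint(mol), dtype=float)


#: Regularization grid searched when C is selected by cross-validation.
_C_GRID = (0.03, 0.1, 0.3, 1.0, 3.0, 10.0)


def train_bbb_svm(
    X: np.ndarray,
    y: np.ndarray,
    n_bits: int = 1024,
    radius: int = 2,
    C: float | None = 1.0,
    seed: int = 0,
) -> BBBModel:
    """Fit a linear soft-margin SVM (hinge loss + L2) on fingerprints.

    Labels are +-1 (+1 = crosses the barrier). ``C=None`` selects the
    regularization strength by 5-fold cross-validation over a fixed grid.
    The fitted hyperplane is extracted into a portable weight/bias
    manifest.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = set(np.unique(y).tolist())
    if classes != {-1, 1}:
        raise TriageError(f"need both classes -1/+1, got {sorted(classes)}")
    if C is None:
        search = GridSearchCV(
            SVC(kernel="linear", random_state=seed), {"C": list(_C_GRID)}, cv=5
        )
        search.fit(X, y)
        svm = search.best_estimator_
    else:
        svm = SVC(kernel="linear", C=C, random_state=seed)
        svm.fit(X, y)
    return BBBModel(
        weights=svm.coef_.ravel(),
        bias=float(svm.intercept_[0]),
        n_bits=n_bits,
        radius=radius,
        seed=seed,
    )


def predict_bbb(mol: Chem.Mol, model: BBBModel) -> tuple[float, bool]:
    """Signed-margin score and the crossing decision (score > 0)."""
    fp = fingerprint(mol, n_bits=model.n_bits, radius=model.radius)
    return predict_bbb_from_bits(fp, model)


def predict_bbb_from_bits(bits: np.ndarray, model: BBBModel) -> tuple[float, bool]:
    bits = np.asarray(bits, dtype=float)
    if bits.shape != (model.n_bits,):
        raise TriageError(
            f"fingerprint length {bits.shape} does not match model n_bits {model.n_bits}"
        )
    score = float(model.weights @ bits + model.bias)
    return score, score > 0.0


def save_bbb_model(model: BBBModel, path: str | Path) -> None:
    payload = {
        "schema_version": 1,
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "n_bits": model.n_bits,
        "radius": model.radius,
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_bbb_model(path: str | Path) -> BBBModel:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("schema_version") != 1:
            raise TriageError(f"unsupported BBB model schema {payload.get('schema_version')!r}")
        return BBBModel(
            weights=np.asarray(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            n_bits=int(payload["n_bits"]),
            radius=int(payload["radius"]),
            seed=int(payload.get("seed", 0)),
        )
    except (OSError, json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise TriageError(f"malformed BBB model file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Triage
# ---------------------------------------------------------------------------


def triage(
    records: Sequence[CompoundRecord],
    rule_config: LipinskiRuleConfig | None = None,
    bbb_model: BBBModel | None = None,
) -> list[TriageVerdict]:
    """Profile, gate, and rank compounds.

    Unparseable records are excluded with a logged reason. Ranking is
    suitable-first, then fewer violations, then higher BBB score, with
    compound name as the final deterministic tie-break. Without a BBB
    model the crossing gate fails for every compound (score 0), so only
    the rule-based ordering applies.
    """
    cfg = rule_config or LipinskiRuleConfig()
    rows: list[dict] = []
    for rec in records:
        try:
            mol = parse_smiles(rec.smiles)
        except TriageError as exc:
            logger.warning("excluding compound %r: %s", rec.name, exc)
            continue
        desc = compute_descriptors(mol)
        violations = lipinski_violations(desc, cfg)
        poor_oral = violations >= cfg.violation_fail_count
        band = clogp_band(desc.clogp)
        if bbb_model is not None:
            bbb_score, crossing = predict_bbb(mol, bbb_model)
        else:
            bbb_score, crossing = 0.0, False
        rows.append(
            {
                "name": rec.name,
                "descriptors": desc,
                "violations": violations,
                "poor_oral": poor_oral,
                "clogp_band": band,
                "bbb_score": bbb_score,
                "bbb_crossing": crossing,
                "suitable": (not poor_oral) and crossing and band == "optimal",
            }
        )
    rows.sort(
        key=lambda r: (not r["suitable"], r["violations"], -r["bbb_score"], r["name"])
    )
    return [TriageVerdict(rank=i + 1, **row) for i, row in enumerate(rows)]
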