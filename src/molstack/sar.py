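"""Structure–activity descriptors and their association with inhibition potency.

Molecular weight is the one descriptor computed here (from an element→count
formula and the IUPAC standard atomic weights); the remaining drug-likeness
descriptors (logP, logS, HBD/HBA counts, aromatic rings, rotatable bonds,
TPSA, flexibility) are consumed from an externally computed property table.
Association between each descriptor and potency is measured by the Spearman
rank correlation against ``-log10(relative concentration)`` — so a positive
coefficient always reads "more of this property, more potent" — with a
permutation null for the p-value.
"""

from __future__ import annotations

import re
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MolstackError

# IUPAC 2021 standard atomic weights (conventional/abridged values), g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.94, "Be": 9.012, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546,
    "Zn": 65.38, "Se": 78.971, "Br": 79.904, "I": 126.904,
}

#: Descriptor columns of the standard property table.
PROPERTY_COLUMNS = (
    "mw", "logp", "logs", "hbd", "hba",
    "aromatic_rings", "rotatable_bonds", "tpsa", "flexibility",
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string like ``"C2H6OS"`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise MolstackError(f"unparseable formula {formula!r} at {pos}")
        pos = match.end()
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula) or not counts:
        raise MolstackError(f"unparseable formula {formula!r}")
    return counts


def molecular_weight(formula: Mapping[str, int] | str) -> float:
    """Molecular weight in g/mol from an element→count map (or formula string).

    Reported to 2 decimals, e.g. DMSO (C2H6OS) → 78.13.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if not formula:
        raise MolstackError("empty formula")
    total = 0.0
    for element, count in formula.items():
        if element not in ATOMIC_WEIGHTS:
            raise MolstackError(f"unknown element symbol {element!r}")
        if count < 0:
            raise MolstackError(f"negative count for element {element!r}")
        total += count * ATOMIC_WEIGHTS[element]
    return round(total, 2)


def potency_score(relative_concentration: float) -> float:
    """Map a relative concentration (mM per 1% inhibition) to a
    higher-is-better potency score, ``-log10(rc)``."""
    if relative_concentration <= 0:
        raise MolstackError("relative concentration must be positive")
    return -float(np.log10(relative_concentration))


def rank_association(
    properties: pd.DataFrame,
    potency: Mapping[str, float],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman association of each descriptor with inhibition potency.

    Parameters
    ----------
    properties
        One row per compound (index = compound name), one column per
        numeric descriptor.
    potency
        compound → relative concentration (mM per 1% inhibition).
        Compounds with undefined potency (``None``/NaN; accelerators and
        non-inhibitors) are excluded.
    n_perm
        Number of label permutations for the p-value (>= 99).
    seed
        Seed of the permutation stream; p-values are bit-reproducible.

    Returns
    -------
    DataFrame with columns ``property, rho, n, p_value, note``, sorted by
    ``|rho|`` descending. Constant descriptor columns are flagged
    undefined rather than dropped silently.
    """
    if n_perm < 99:
        raise MolstackError("n_perm must be >= 99")
    usable = {
        c: rc for c, rc in potency.items()
        if rc is not None and np.isfinite(rc) and rc > 0 and c in properties.index
    }
    if len(usable) < 4:
        raise MolstackError(
            f"need >=4 compounds with both descriptors and defined potency, got {len(usable)}"
        )
    compounds = sorted(usable)
    score = np.array([potency_score(usable[c]) for c in compounds])
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(len(score)) for _ in range(n_perm)]

    rows = []
    for prop in properties.columns:
        values = properties.loc[compounds, prop].to_numpy(dtype=float)
        if np.all(values == values[0]):
            rows.append({"property": prop, "rho": np.nan, "n": len(values),
                         "p_value": np.nan, "note": "constant descriptor"})
            continue
        rho = stats.spearmanr(values, score).statistic
        exceed = sum(
            1 for p in perms
            if abs(stats.spearmanr(values, score[p]).statistic) >= abs(rho) - 1e-12
        )
        rows.append({"property": prop, "rho": float(rho), "n": len(values),
                     "p_value": (exceed + 1) / (n_perm + 1), "note": ""})
    result = pd.DataFrame(rows)
    return result.reindex(
        result["rho"].abs().sort_values(ascending=False, na_position="last").index
    ).reset_index(drop=True)
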