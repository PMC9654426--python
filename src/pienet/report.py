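"""Regression analytics and table rendering for interaction-energy sets.

The central operation is an ordinary least-squares regression of one
interaction-energy set on another (QM on MM by convention), with R^2 the
squared Pearson correlation, after dropping pairs excluded by rule —
typically the covalently linked pair, whose force-field value is distorted
by the bonded-neighbour exclusions while the QM value is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .system import GroupScheme, MolecularSystem, UnitScheme

__all__ = [
    "RegressionResult",
    "regress",
    "component_correlation",
    "bond_distance_stats",
    "make_report",
    "format_mean_std",
]


@dataclass
class RegressionResult:
    """OLS fit of y on x with the excluded keys and their reasons."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    stderr: float = np.nan
    excluded: List[Tuple[object, str]] = field(default_factory=list)

    def slope_ci(self, confidence: float = 0.95) -> Tuple[float, float]:
        """Two-sided t confidence interval for the slope."""
        t = stats.t.ppf(0.5 + confidence / 2, self.n - 2)
        return self.slope - t * self.stderr, self.slope + t * self.stderr


def regress(
    x: pd.Series,
    y: pd.Series,
    exclude: Optional[Dict[object, str]] = None,
) -> RegressionResult:
    """OLS of y on x over index-aligned keys, minus the excluded ones.

    ``exclude`` maps key -> reason (e.g. {"Met107:Asp108": "covalent"}).
    Keys present in only one series are dropped listwise.
    """
    x = pd.Series(x).astype(float)
    y = pd.Series(y).astype(float)
    y_keys = set(y.index)
    keys = [k for k in x.index if k in y_keys]
    excluded: List[Tuple[object, str]] = []
    if exclude:
        excluded = [(k, exclude[k]) for k in keys if k in exclude]
        keys = [k for k in keys if k not in exclude]
    xv = np.array([x[k] for k in keys], dtype=float)
    yv = np.array([y[k] for k in keys], dtype=float)
    mask = np.isfinite(xv) & np.isfinite(yv)
    dropped = [(k, "missing value") for k, ok in zip(keys, mask) if not ok]
    xv, yv = xv[mask], yv[mask]
    if len(xv) < 2:
        raise ValueError(f"need at least 2 points to regress, got {len(xv)}")
    fit = stats.linregress(xv, yv)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        n=int(len(xv)),
        stderr=float(fit.stderr),
        excluded=excluded + dropped,
    )


def component_correlation(
    mm_table: pd.DataFrame,
    qm_table: pd.DataFrame,
    key_col: str = "pair",
    exclude_covalent: bool = True,
) -> Dict[str, RegressionResult]:
    """Paired regressions of QM components on their MM counterparts.

    Matches ES against elec and DI against vdw over shared pair keys, with
    covalent pairs excluded by default.  Input frames need ``key_col`` plus
    the respective component columns (and optionally ``is_covalent``).
    """
    mm = mm_table.set_index(key_col)
    qm = qm_table.set_index(key_col)
    exclude: Dict[object, str] = {}
    if exclude_covalent:
        for frame in (mm, qm):
            if "is_covalent" in frame.columns:
                for key in frame.index[frame["is_covalent"].astype(bool)]:
                    exclude[key] = "covalent pair"
    return {
        "elec_vs_ES": regress(mm["elec"], qm["ES"], exclude=exclude),
        "vdw_vs_DI": regress(mm["vdw"], qm["DI"], exclude=exclude),
    }


def bond_distance_stats(
    system: MolecularSystem,
    scheme: UnitScheme,
    unit_i: int,
    unit_j: int,
    groups: GroupScheme,
    snapshots: Optional[Sequence[int]] = None,
    population: bool = True,
) -> pd.DataFrame:
    """Ensemble mean +/- std of the probe heavy-atom distance per named bond.

    Each bond's probe atoms are resolved by name in whichever of the two
    units contains them.  Returns columns bond, mean, std, n.
    """
    if system.snapshots is None:
        raise ValueError("system carries no snapshots")
    if snapshots is None:
        snapshots = range(system.snapshots.n_frames)
    snapshots = list(snapshots)
    atoms_i = scheme.atoms_of(unit_i)
    atoms_j = scheme.atoms_of(unit_j)
    name_of = system.names

    def resolve(name: str):
        hits_i = [a for a in atoms_i if name_of[a] == name]
        hits_j = [a for a in atoms_j if name_of[a] == name]
        return hits_i + hits_j

    rows = []
    ddof = 0 if population else 1
    for bond, (name_a, name_b) in groups.probe_atoms.items():
        cand_a, cand_b = resolve(name_a), resolve(name_b)
        if not cand_a or not cand_b:
            missing = name_a if not cand_a else name_b
            raise KeyError(
                f"bond {bond!r}: probe atom {missing!r} not found in units "
                f"{scheme.unit_labels[unit_i]} / {scheme.unit_labels[unit_j]}"
            )
        # probe atoms must sit in opposite units; a name may exist in both
        a = b = None
        set_i, set_j = set(atoms_i.tolist()), set(atoms_j.tolist())
        for ca in cand_a:
            opposite = set_j if ca in set_i else set_i
            hits = [cb for cb in cand_b if cb in opposite]
            if hits:
                a, b = ca, hits[0]
                break
        if a is None:
            raise KeyError(
                f"bond {bond!r}: probe atoms {name_a!r}/{name_b!r} resolve to "
                "the same unit"
            )
        d = np.linalg.norm(
            system.snapshots.coords[snapshots, a, :]
            - system.snapshots.coords[snapshots, b, :],
            axis=1,
        )
        rows.append(
            {"bond": bond, "mean": float(d.mean()),
             "std": float(d.std(ddof=ddof)), "n": len(snapshots)}
        )
    return pd.DataFrame(rows, columns=["bond", "mean", "std", "n"])


def format_mean_std(mean: float, std: Optional[float] = None, decimals: int = 1) -> str:
    """Render "mean±std" at fixed precision; empty string for absent cells."""
    if mean is None or (isinstance(mean, float) and np.isnan(mean)):
        return ""
    if std is None or (isinstance(std, float) and np.isnan(std)):
        return f"{mean:.{decimals}f}"
    return f"{mean:.{decimals}f}±{std:.{decimals}f}"


def make_report(
    tables: Dict[str, pd.DataFrame],
    decimals: int = 1,
    outdir=None,
) -> Dict[str, pd.DataFrame]:
    """Render mean/std table pairs into fixed-precision display tables.

    ``tables`` maps a table name to a frame whose ``*_mean`` / ``*_std``
    column pairs are collapsed into "mean±std" strings rounded to
    ``decimals``; other columns pass through.  Absent cells (NaN means,
    e.g. a glycine ff block) render as empty strings.  With ``outdir``
    each rendered table is also written as ``<name>.csv`` — byte-identical
    across reruns on identical input.
    """
    rendered: Dict[str, pd.DataFrame] = {}
    for name, frame in tables.items():
        out = {}
        done = set()
        for col in frame.columns:
            if col in done:
                continue
            if col.endswith("_mean"):
                stem = col[: -len("_mean")]
                std_col = f"{stem}_std"
                if std_col in frame.columns:
                    out[stem] = [
                        format_mean_std(m, s, decimals)
                        for m, s in zip(frame[col], frame[std_col])
                    ]
                    done |= {col, std_col}
                    continue
            if col.endswith("_std"):
                continue
            out[col] = frame[col]
        rendered[name] = pd.DataFrame(out)
        if outdir is not None:
            import pathlib

            rendered[name].to_csv(pathlib.Path(outdir) / f"{name}.csv", index=False)
    return rendered
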