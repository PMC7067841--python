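"""Composition statistics on lipid species abundance tables.

The analysis chain mirrors standard shotgun-lipidomics post-processing:
picomole abundances are transformed to mol%, storage lipids (TAG, sterol
esters) are removed for "membrane" scope, and a further restriction to
glycerophospholipids (GPL) supports acyl-chain statistics.  On mol%
lipidomes the module computes concentration-weighted unsaturation indices,
"remaining-lipid" analyses after excluding a supplemented fatty acid and
its metabolic derivatives, saturation profiles, class composition, and
condition-level fold changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import AcylChain, LipidSpecies, chains_of, parse_species

logger = logging.getLogger(__name__)

__all__ = [
    "LipidomeSample",
    "MolPercentLipidome",
    "FattyAcidSet",
    "SaturationProfile",
    "UnsaturationIndexResult",
    "FoldChange",
    "OMEGA3_SET",
    "OMEGA6_SET",
    "normalize",
    "unsaturation_index",
    "exclude_set",
    "fraction_containing",
    "species_contains",
    "saturation_profile",
    "class_composition",
    "condition_fold_change",
    "read_abundance_table",
]

_SUM_TOL = 1e-9

# Double-bond histogram: counts of 7 and above share the top bin.
MAX_DB_BIN = 7


@dataclass(frozen=True)
class FattyAcidSet:
    """A named set of acyl-chain (carbons, double_bonds) signatures."""

    label: str
    members: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("fatty-acid set must be non-empty")

    def __contains__(self, chain: AcylChain | tuple[int, int]) -> bool:
        if isinstance(chain, AcylChain):
            chain = chain.signature
        return tuple(chain) in self.members


#: Supplemented fatty acid plus retroconversion products.  DHA (22:6) is
#: retro-converted to EPA (20:5), which elongates to 24:6; AA (20:4) is
#: converted to 22:4 and 24:4.
OMEGA3_SET = FattyAcidSet("omega-3", frozenset({(22, 6), (20, 5), (24, 6)}))
OMEGA6_SET = FattyAcidSet("omega-6", frozenset({(20, 4), (22, 4), (24, 4)}))

#: Classes kept in GPL scope: glycerophospholipids incl. lyso/ether variants
#: and cardiolipin.
GPL_SCOPE_EXCLUDES = {"Chol", "SM", "Cer", "HexCer", "DiHexCer", "DAG", "CL"}


@dataclass
class LipidomeSample:
    """Species -> pmol abundances for one measured sample."""

    sample_id: str
    abundances: dict[LipidSpecies, float]
    condition: str = ""
    replicate: int = 0
    time_h: Optional[float] = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        if not any(v > 0 for v in self.abundances.values()):
            raise ValueError("sample needs at least one species with abundance > 0")


@dataclass
class MolPercentLipidome:
    """Species -> mol% within a scope; values sum to 100."""

    scope: str  # "all" | "membrane" | "GPL"
    abundances: dict[LipidSpecies, float]
    sample_id: str = ""
    condition: str = ""
    replicate: int = 0
    time_h: Optional[float] = None

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if not math.isclose(total, 100.0, abs_tol=1e-6):
            raise ValueError(f"mol% must sum to 100, got {total}")

    def species(self) -> list[LipidSpecies]:
        return list(self.abundances)


@dataclass
class UnsaturationIndexResult:
    """Concentration-weighted mean double bonds per lipid."""

    value: float
    scope: str
    n_species: int
    excluded_label: Optional[str] = None


@dataclass
class SaturationProfile:
    """Species- and chain-level saturation statistics of a lipidome."""

    distribution: dict[int, float]  # total double bonds (7 = 7+) -> mol%
    fully_saturated_species_pct: float
    saturated_chain_pct: Optional[float]
    high_unsat_chain_pct: Optional[float]
    unresolved_abundance_pct: float


@dataclass
class FoldChange:
    """Ratio of group means with delta-method propagated SD."""

    fold: float
    sd: float
    n_a: int
    n_b: int


def _scope_keep(species: LipidSpecies, scope: str) -> bool:
    cls = species.lipid_class
    if scope == "all":
        return True
    if scope == "membrane":
        return not cls.is_storage
    if scope == "GPL":
        return cls.is_glycerophospholipid and cls.name != "CL"
    raise ValueError(f"unknown scope {scope!r}")


def normalize(
    sample: LipidomeSample | MolPercentLipidome, scope: str = "membrane"
) -> MolPercentLipidome:
    """Transform abundances to mol% of the scoped lipid total.

    ``membrane`` drops TAG and SE before renormalizing; ``GPL`` further
    restricts to glycerophospholipid classes (excluding cardiolipin, whose
    four chains make per-chain statistics incommensurate with diacyl GPLs;
    configurable via :data:`GPL_SCOPE_EXCLUDES` semantics).
    """
    kept = {s: v for s, v in sample.abundances.items() if _scope_keep(s, scope)}
    total = sum(kept.values())
    if total <= 0:
        raise ValueError(f"no abundance left in scope {scope!r}")
    return MolPercentLipidome(
        scope=scope,
        abundances={s: 100.0 * v / total for s, v in kept.items()},
        sample_id=getattr(sample, "sample_id", ""),
        condition=getattr(sample, "condition", ""),
        replicate=getattr(sample, "replicate", 0),
        time_h=getattr(sample, "time_h", None),
    )


def unsaturation_index(
    lipidome: MolPercentLipidome, excluded_label: Optional[str] = None
) -> UnsaturationIndexResult:
    """Concentration-weighted average double bonds per lipid.

    Cholesterol carries no acyl chains and is excluded from the average
    (with a logged note); weights are the mol% of the remaining species.
    """
    pairs = [
        (w, s.total_double_bonds)
        for s, w in lipidome.abundances.items()
        if s.lipid_class.has_composition
    ]
    n_dropped = len(lipidome.abundances) - len(pairs)
    if n_dropped:
        logger.info("unsaturation_index: excluded %d composition-free species", n_dropped)
    wsum = sum(w for w, _ in pairs)
    if wsum <= 0:
        raise ValueError("all included species have zero weight")
    value = sum(w * db for w, db in pairs) / wsum
    return UnsaturationIndexResult(value, lipidome.scope, len(pairs), excluded_label)


def species_contains(species: LipidSpecies, fa_set: FattyAcidSet) -> bool:
    """Chain-level containment of any set member.

    Sum-only species are judged only when their class forces a single
    chain; multi-chain species without resolution are treated as not
    containing the member (the unresolved abundance is reported by
    :func:`saturation_profile` so users can bound the error).
    """
    chains = chains_of(species)
    if chains is None:
        return False
    return any(c in fa_set for c in chains)


def exclude_set(
    lipidome: MolPercentLipidome, excluded: FattyAcidSet
) -> MolPercentLipidome:
    """Remove species containing any member chain; renormalize to 100 mol%.

    This is the "remaining lipids" analysis: the supplemented fatty acid
    and its derivatives are dropped so compensatory remodeling of the rest
    of the lipidome is not masked by their over-abundance.
    """
    kept = {
        s: v
        for s, v in lipidome.abundances.items()
        if not species_contains(s, excluded)
    }
    total = sum(kept.values())
    if total <= 0:
        raise ValueError(f"excluding {excluded.label} removed every lipid")
    out = MolPercentLipidome(
        scope=lipidome.scope,
        abundances={s: 100.0 * v / total for s, v in kept.items()},
        sample_id=lipidome.sample_id,
        condition=lipidome.condition,
        replicate=lipidome.replicate,
        time_h=lipidome.time_h,
    )
    return out


def fraction_containing(lipidome: MolPercentLipidome, chains: FattyAcidSet) -> float:
    """Summed mol% of species containing at least one member chain."""
    return sum(
        v for s, v in lipidome.abundances.items() if species_contains(s, chains)
    )


def saturation_profile(lipidome: MolPercentLipidome) -> SaturationProfile:
    """Species-level double-bond distribution plus chain-level saturation.

    The distribution bins species by total double bonds (top bin pools
    >= 7).  Chain-level percentages (fraction of acyl chains with 0 double
    bonds, and with 5-6 double bonds) are abundance-weighted over
    chain-resolved species only; the mol% of unresolved abundance is
    reported alongside.
    """
    if lipidome.scope != "GPL":
        logger.warning(
            "saturation_profile computed on scope %r; GPL scope is the "
            "conventional basis for acyl-chain statistics",
            lipidome.scope,
        )
    dist: dict[int, float] = {}
    sat0 = 0.0
    chain_total = 0.0
    chain_sat = 0.0
    chain_high = 0.0
    resolved_w = 0.0
    total_w = 0.0
    for s, w in lipidome.abundances.items():
        if not s.lipid_class.has_composition:
            continue
        total_w += w
        b = min(s.total_double_bonds, MAX_DB_BIN)
        dist[b] = dist.get(b, 0.0) + w
        if s.total_double_bonds == 0:
            sat0 += w
        chains = chains_of(s)
        if chains is not None:
            resolved_w += w
            for c in chains:
                chain_total += w
                if c.double_bonds == 0:
                    chain_sat += w
                elif c.double_bonds in (5, 6):
                    chain_high += w
    if total_w <= 0:
        raise ValueError("no species with composition in lipidome")
    norm = 100.0 / total_w
    dist = {b: v * norm for b, v in dist.items()}
    if chain_total > 0:
        sat_chain_pct = 100.0 * chain_sat / chain_total
        high_chain_pct = 100.0 * chain_high / chain_total
    else:
        sat_chain_pct = high_chain_pct = None
    return SaturationProfile(
        distribution=dist,
        fully_saturated_species_pct=sat0 * norm,
        saturated_chain_pct=sat_chain_pct,
        high_unsat_chain_pct=high_chain_pct,
        unresolved_abundance_pct=(1.0 - resolved_w / total_w) * 100.0,
    )


def class_composition(lipidome: MolPercentLipidome) -> dict[str, float]:
    """Aggregate species mol% by lipid class (headgroup profile).

    The ``Chol`` entry is the membrane-cholesterol statistic used for
    sterol-level comparisons.
    """
    out: dict[str, float] = {}
    for s, v in lipidome.abundances.items():
        out[s.lipid_class.name] = out.get(s.lipid_class.name, 0.0) + v
    return out


def condition_fold_change(
    group_a: Sequence[float], group_b: Sequence[float]
) -> FoldChange:
    """mean(a)/mean(b) with delta-method SD.

    Var(f) ~ Var(mean_a)/mean_b^2 + mean_a^2 Var(mean_b)/mean_b^4 for
    independent groups; SD of a single-observation group is taken as 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ma, mb = a.mean(), b.mean()
    if mb <= 0:
        raise ValueError("denominator group mean must be > 0")
    va = a.var(ddof=1) / a.size if a.size > 1 else 0.0
    vb = b.var(ddof=1) / b.size if b.size > 1 else 0.0
    sd = math.sqrt(va / mb**2 + (ma**2) * vb / mb**4)
    return FoldChange(fold=ma / mb, sd=sd, n_a=a.size, n_b=b.size)


def statistics_table(
    samples: Iterable[LipidomeSample],
    fa_set: FattyAcidSet = OMEGA3_SET,
    scope: str = "GPL",
) -> pd.DataFrame:
    """Tidy per-sample statistics (one row per sample x statistic).

    For each sample: the mol% of species containing the fatty-acid set,
    the unsaturation index, the "remaining" unsaturation index after
    excluding the set, and the fully saturated species mol%, all within
    the requested scope.
    """
    rows = []
    for sample in samples:
        lip = normalize(sample, scope)
        stats = {
            f"fraction_containing_{fa_set.label}": fraction_containing(lip, fa_set),
            "unsaturation_index": unsaturation_index(lip).value,
            "unsaturation_index_remaining": unsaturation_index(
                exclude_set(lip, fa_set), excluded_label=fa_set.label
            ).value,
            "fully_saturated_species_pct": saturation_profile(
                lip
            ).fully_saturated_species_pct,
        }
        for stat, value in stats.items():
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "condition": sample.condition,
                    "replicate": sample.replicate,
                    "time_h": sample.time_h,
                    "scope": scope,
                    "statistic": stat,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def condition_summary(table: pd.DataFrame) -> dict:
    """Per-condition mean +/- SD of each statistic from a tidy table."""
    out: dict = {}
    for (cond, stat), grp in table.groupby(["condition", "statistic"]):
        vals = grp["value"].to_numpy(dtype=float)
        out.setdefault(cond, {})[stat] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            "n": int(vals.size),
        }
    return out


# ---------------------------------------------------------------------------
# Table input
# ---------------------------------------------------------------------------

def read_abundance_table(
    path: str | Path,
    metadata: Optional[str | Path | pd.DataFrame] = None,
    sep: Optional[str] = None,
) -> list[LipidomeSample]:
    """Read a species x sample pmol table (CSV/TSV) into samples.

    First column ``species`` holds names in sum-composition or
    chain-resolved nomenclature; remaining columns are one sample each.
    ``metadata`` is an optional sidecar (CSV or DataFrame) with columns
    ``sample_id, condition, replicate[, time_h]``.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    first = df.columns[0]
    df = df.set_index(first)
    species = [parse_species(str(n)) for n in df.index]

    meta = {}
    if metadata is not None:
        mdf = (
            metadata
            if isinstance(metadata, pd.DataFrame)
            else pd.read_csv(metadata)
        )
        for _, row in mdf.iterrows():
            meta[str(row["sample_id"])] = row

    samples = []
    for col in df.columns:
        abund = {
            sp: float(v)
            for sp, v in zip(species, df[col].to_numpy())
            if np.isfinite(v) and v > 0
        }
        row = meta.get(str(col))
        samples.append(
            LipidomeSample(
                sample_id=str(col),
                abundances=abund,
                condition=str(row["condition"]) if row is not None else "",
                replicate=int(row["replicate"]) if row is not None else 0,
                time_h=(
                    float(row["time_h"])
                    if row is not None and "time_h" in row and pd.notna(row["time_h"])
                    else None
                ),
            )
        )
    return samples
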