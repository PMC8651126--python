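"""Efficiency-of-plating normalization, host-range profiles and the hs
(shared sensitive hosts / union of sensitive hosts) statistic.

An EOP matrix is a viruses-by-hosts pandas DataFrame of non-negative
plating efficiencies (raw titers or already-normalized ratios), with an
isolation host recorded per virus.  Normalization divides each virus row
by its titer on the isolation host (set to 1); a per-virus substitute
reference titer may stand in when the isolation host is absent from the
panel.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

NOT_INFECTED = None  # sentinel category for zero EOP
_SENTINEL_CATEGORY = -9  # numeric stand-in used for host clustering


@dataclass
class EOPMatrix:
    values: pd.DataFrame  # viruses x hosts, raw EOP values >= 0
    isolation_host: dict[str, str]
    substitute_titer: dict[str, float] = field(default_factory=dict)
    detection_floor: float = 0.0  # raw titers at or below this are set to 0

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("EOP values must be non-negative")
        for virus in self.values.index:
            if virus not in self.isolation_host and virus not in self.substitute_titer:
                raise ValueError(f"virus {virus} has no isolation host or substitute titer")
            host = self.isolation_host.get(virus)
            if host is not None and host not in self.values.columns \
                    and virus not in self.substitute_titer:
                raise ValueError(
                    f"isolation host {host!r} of {virus} absent from panel "
                    "and no substitute titer supplied")


def normalize_eop(matrix: EOPMatrix) -> pd.DataFrame:
    """Divide each virus row by its isolation-host titer (set to 1).

    Idempotent: normalizing a normalized matrix changes nothing.  Values
    at or below the detection floor are zeroed before normalization.
    """
    vals = matrix.values.copy().astype(float)
    if matrix.detection_floor > 0:
        vals[vals <= matrix.detection_floor] = 0.0
    for virus in vals.index:
        host = matrix.isolation_host.get(virus)
        if virus in matrix.substitute_titer:
            ref = matrix.substitute_titer[virus]
        elif host in vals.columns:
            ref = float(vals.loc[virus, host])
        else:
            ref = 0.0
        if ref <= 0:
            raise ValueError(
                f"virus {virus}: isolation-host titer is zero/missing and no "
                "substitute reference titer was supplied")
        vals.loc[virus] = vals.loc[virus] / ref
    return vals


def bin_log10(normalized: pd.DataFrame) -> pd.DataFrame:
    """Round-half-away-from-zero log10 categories; zeros become NaN
    ("not infected").  Category 0 corresponds to the isolation-host EOP."""
    arr = normalized.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("normalized EOP values must be non-negative")
    out = np.full(arr.shape, np.nan)
    pos = arr > 0
    logs = np.log10(arr[pos])
    # round half away from zero
    out[pos] = np.sign(logs) * np.floor(np.abs(logs) + 0.5)
    return pd.DataFrame(out, index=normalized.index, columns=normalized.columns)


def format_category(cat: float) -> str:
    if cat is None or (isinstance(cat, float) and math.isnan(cat)):
        return "-"
    cat = int(cat)
    if cat == 0:
        return "1"
    return f"+{cat}" if cat > 0 else str(cat)


def sensitive_hosts(normalized: pd.DataFrame) -> dict[str, frozenset]:
    """Virus -> set of hosts with any detectable plating (value > 0)."""
    return {virus: frozenset(normalized.columns[normalized.loc[virus] > 0])
            for virus in normalized.index}


def hs(profile_a: frozenset, profile_b: frozenset, denominator: str = "union") -> float:
    """Shared sensitive hosts over total sensitive hosts of the pair.

    ``denominator`` is "union" (Jaccard; default) or "sum".
    """
    inter = len(profile_a & profile_b)
    if denominator == "union":
        total = len(profile_a | profile_b)
    elif denominator == "sum":
        total = len(profile_a) + len(profile_b)
    else:
        raise ValueError("denominator must be 'union' or 'sum'")
    if total == 0:
        warnings.warn("hs of two empty host-range profiles; defined as 0")
        return 0.0
    return inter / total


def hs_matrix(profiles: dict[str, frozenset], denominator: str = "union") -> pd.DataFrame:
    ids = sorted(profiles)
    n = len(ids)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = hs(profiles[ids[i]], profiles[ids[j]], denominator)
    return pd.DataFrame(m, index=ids, columns=ids)


def cluster_hosts(categories: pd.DataFrame) -> str:
    """Average-linkage Newick dendrogram of hosts from Manhattan distances
    between category columns (the not-infected sentinel scored as -9)."""
    if categories.shape[1] < 2:
        raise ValueError("need at least 2 hosts")
    cols = categories.fillna(_SENTINEL_CATEGORY).to_numpy().T
    hosts = list(categories.columns)
    link = average(pdist(cols, metric="cityblock"))
    nodes = [f"{h}" for h in hosts]
    heights = [0.0] * len(hosts)
    for row in link:
        a, b, dist, _ = int(row[0]), int(row[1]), row[2] / 2.0, row[3]
        nodes.append(f"({nodes[a]}:{dist - heights[a]:.6g},{nodes[b]}:{dist - heights[b]:.6g})")
        heights.append(dist)
    return nodes[-1] + ";"


def _condensed(matrix: pd.DataFrame, ids: list[str]) -> np.ndarray:
    return np.array([matrix.loc[a, b] for a, b in itertools.combinations(ids, 2)])


@dataclass
class AdhesinAssociation:
    rho_overall: float
    p_overall: float
    per_group: pd.DataFrame  # group, n_viruses, rho, p


def associate_adhesin(hs_mat: pd.DataFrame, identity_mat: pd.DataFrame,
                      groups: dict[str, int] | None = None,
                      n_perm: int = 999, seed: int = 0) -> AdhesinAssociation:
    """Spearman correlation between pairwise hs and adhesin identity with a
    Mantel-style permutation test (virus labels permuted jointly).

    This significance test is an extension of the published heat-map
    comparison; p = (1 + #permutations >= observed) / (n_perm + 1).
    """
    ids = sorted(hs_mat.index)
    if sorted(identity_mat.index) != ids:
        raise ValueError("hs and identity matrices must cover the same viruses")
    if len(ids) < 4:
        raise ValueError("need at least 4 viruses")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    hs_m = hs_mat.loc[ids, ids].to_numpy()
    id_m = identity_mat.loc[ids, ids].to_numpy()
    iu = np.triu_indices(len(ids), k=1)

    def rho_of(perm: np.ndarray) -> float:
        permuted = id_m[np.ix_(perm, perm)]
        r = spearmanr(hs_m[iu], permuted[iu]).statistic
        return 0.0 if np.isnan(r) else float(r)

    obs = rho_of(np.arange(len(ids)))
    count = sum(rho_of(rng.permutation(len(ids))) >= obs for _ in range(n_perm))
    p_overall = (1 + count) / (n_perm + 1)

    rows = []
    if groups:
        for grp in sorted(set(groups.values())):
            members = [v for v in ids if groups.get(v) == grp]
            if len(members) < 4:
                rows.append({"group": grp, "n_viruses": len(members),
                             "rho": np.nan, "p": np.nan})
                continue
            sub_hs = hs_mat.loc[members, members]
            sub_id = identity_mat.loc[members, members]
            sub = associate_adhesin(sub_hs, sub_id, groups=None,
                                    n_perm=n_perm, seed=seed + grp)
            rows.append({"group": grp, "n_viruses": len(members),
                         "rho": sub.rho_overall, "p": sub.p_overall})
    per_group = pd.DataFrame(rows, columns=["group", "n_viruses", "rho", "p"])
    return AdhesinAssociation(obs, p_overall, per_group)


# ---------------------------------------------------------------------------
# I/O


def read_eop_table(values_path, isolation_path, detection_floor: float = 0.0) -> EOPMatrix:
    """Tab-separated virus x host table plus two-column isolation-host map.

    A third column in the isolation map, when present and non-empty, is a
    substitute reference titer for viruses whose isolation host is not in
    the panel.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    isolation: dict[str, str] = {}
    substitute: dict[str, float] = {}
    with open(isolation_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            isolation[parts[0]] = parts[1]
            if len(parts) > 2 and parts[2]:
                substitute[parts[0]] = float(parts[2])
    return EOPMatrix(values, isolation, substitute, detection_floor)


def write_category_table(categories: pd.DataFrame, path) -> None:
    display = categories.map(format_category)
    display.to_csv(path, sep="\t")
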