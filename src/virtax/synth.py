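"""Seeded synthetic-data generators with ground-truth labels.

Every pipeline input can be generated here: multi-family genome sets with
calibrated shared-gene fractions, EOP matrices structured by adhesin
group, genomes with a tunable motif-depletion factor, and host contigs
with planted proviruses flanked by direct repeats.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable

from .genome_io import Genome, GeneRecord, revcomp
from .host_range import EOPMatrix
from .motifs import count_motif, expected_count_markov, fit_markov

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in _TABLE11.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()
_STOPS = sorted(_TABLE11.stop_codons)

DEFAULT_GC = 0.62  # haloarchaeal genomes are GC-rich


def _dna(rng: np.random.Generator, length: int, gc: float = DEFAULT_GC) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)])


def _mutate_protein(seq: str, retention: float, rng: np.random.Generator) -> str:
    """Per-site substitution: keep with probability ``retention``, else draw
    uniformly from the other 19 residues."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) >= retention)[0]
    for i in hits:
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def retention_for_pairwise_identity(target: float) -> float:
    """Per-lineage retention p so that two sequences independently evolved
    from a common ancestor have expected identity ``target``:
    t = p^2 + (1-p)^2 / 19."""
    if not 0 < target <= 1:
        raise ValueError("target identity must be in (0, 1]")
    a, b, c = 20.0 / 19.0, -2.0 / 19.0, 1.0 / 19.0 - target
    disc = b * b - 4 * a * c
    p = (-b + math.sqrt(disc)) / (2 * a)
    return min(p, 1.0)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice, table 11, with a trailing stop."""
    codons = [
        _CODONS_FOR[aa][rng.integers(0, len(_CODONS_FOR[aa]))] for aa in protein
    ]
    codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# Taxonomy genome sets


@dataclass
class SyntheticTruth:
    seed: int
    parameters: dict
    families: dict[str, str] = field(default_factory=dict)  # genome -> family
    genera: dict[str, str] = field(default_factory=dict)  # genome -> genus
    gene_families: dict[str, str] = field(default_factory=dict)  # protein id -> planted PC
    adhesin_groups: dict[str, int] = field(default_factory=dict)
    susceptibility: dict[int, list[str]] = field(default_factory=dict)
    depletion_factors: dict[str, float] = field(default_factory=dict)
    proviruses: list[dict] = field(default_factory=list)

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "parameters": self.parameters,
            "families": self.families,
            "genera": self.genera,
            "gene_families": self.gene_families,
            "adhesin_groups": self.adhesin_groups,
            "susceptibility": self.susceptibility,
            "depletion_factors": self.depletion_factors,
            "proviruses": self.proviruses,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            seed=data["seed"], parameters=data.get("parameters", {}),
            families=data.get("families", {}), genera=data.get("genera", {}),
            gene_families=data.get("gene_families", {}),
            adhesin_groups=data.get("adhesin_groups", {}),
            susceptibility=data.get("susceptibility", {}),
            depletion_factors=data.get("depletion_factors", {}),
            proviruses=data.get("proviruses", []),
        )


def gen_taxonomy_set(n_families: int = 3, genera_per_family: int = 2,
                     genomes_per_genus: int = 4,
                     family_core: int = 15, genus_core: int = 20,
                     private_genes: int = 10,
                     within_genus_identity: float = 0.75,
                     within_family_identity: float = 0.45,
                     protein_len_range: tuple[int, int] = (200, 300),
                     spacer_range: tuple[int, int] = (50, 150),
                     gc: float = DEFAULT_GC,
                     seed: int = 0) -> tuple[list[Genome], SyntheticTruth]:
    """Genomes with planted two-rank taxonomy.

    Family-core genes descend from a per-family ancestral protein through
    genus ancestors; genus-core genes from per-genus ancestors; private
    genes are genome-specific random proteins.  Per-branch retentions are
    solved so that expected pairwise identity is ``within_genus_identity``
    inside a genus and ``within_family_identity`` across genera of a
    family.
    """
    if not 0 < within_family_identity < within_genus_identity < 1:
        raise ValueError("identities must satisfy 0 < within_family < within_genus < 1")
    rng = np.random.default_rng(seed)
    p_leaf = retention_for_pairwise_identity(within_genus_identity)
    p_eff = retention_for_pairwise_identity(within_family_identity)
    p_genus_branch = p_eff / p_leaf
    if p_genus_branch > 1:
        raise ValueError("inconsistent identity targets")

    truth = SyntheticTruth(seed=seed, parameters={
        "n_families": n_families, "genera_per_family": genera_per_family,
        "genomes_per_genus": genomes_per_genus, "family_core": family_core,
        "genus_core": genus_core, "private_genes": private_genes,
        "within_genus_identity": within_genus_identity,
        "within_family_identity": within_family_identity, "gc": gc,
    })
    genomes: list[Genome] = []
    for fi in range(1, n_families + 1):
        lens_fam = rng.integers(protein_len_range[0], protein_len_range[1] + 1,
                                size=family_core)
        fam_anc = [_random_protein(rng, ln) for ln in lens_fam]
        for gi in range(1, genera_per_family + 1):
            genus_anc_fam = [_mutate_protein(p, p_genus_branch, rng) for p in fam_anc]
            lens_gen = rng.integers(protein_len_range[0], protein_len_range[1] + 1,
                                    size=genus_core)
            genus_anc_own = [_random_protein(rng, ln) for ln in lens_gen]
            for vi in range(1, genomes_per_genus + 1):
                gid = f"V{fi}{gi}{vi:02d}"
                proteins: list[tuple[str, str, str]] = []  # (planted PC, gene name, aa)
                for k, anc in enumerate(genus_anc_fam):
                    proteins.append((f"famPC_{fi}_{k}", f"g{k + 1:03d}",
                                     _mutate_protein(anc, p_leaf, rng)))
                for k, anc in enumerate(genus_anc_own):
                    proteins.append((f"genPC_{fi}_{gi}_{k}", f"g{family_core + k + 1:03d}",
                                     _mutate_protein(anc, p_leaf, rng)))
                for k in range(private_genes):
                    ln = int(rng.integers(protein_len_range[0], protein_len_range[1] + 1))
                    proteins.append((f"priv_{gid}_{k}",
                                     f"g{family_core + genus_core + k + 1:03d}",
                                     _random_protein(rng, ln)))
                parts: list[str] = []
                genes: list[GeneRecord] = []
                pos = 0
                for pc_label, gene_name, aa in proteins:
                    spacer = _dna(rng, int(rng.integers(*spacer_range)), gc)
                    parts.append(spacer)
                    pos += len(spacer)
                    strand = "+" if rng.random() < 0.8 else "-"
                    cds = back_translate(aa, rng)
                    nt = cds if strand == "+" else revcomp(cds)
                    genes.append(GeneRecord(gene_id=gene_name, genome_id=gid,
                                            start=pos, end=pos + len(nt),
                                            strand=strand, protein=aa,
                                            product="synthetic protein"))
                    parts.append(nt)
                    pos += len(nt)
                    truth.gene_families[f"{gid}|{gene_name}"] = pc_label
                parts.append(_dna(rng, int(rng.integers(*spacer_range)), gc))
                genomes.append(Genome(id=gid, sequence="".join(parts),
                                      name=f"synthetic virus {gid}", genes=genes))
                truth.families[gid] = f"F{fi}"
                truth.genera[gid] = f"F{fi}G{gi}"
    return genomes, truth


# ---------------------------------------------------------------------------
# EOP matrices


def default_susceptibility(adhesin_groups: int, hosts: list[str]) -> dict[int, list[str]]:
    """Disjoint host blocks per adhesin group (remainder hosts unused)."""
    block = len(hosts) // adhesin_groups
    return {g + 1: hosts[g * block : (g + 1) * block] for g in range(adhesin_groups)}


def gen_eop_matrix(adhesin_groups: int = 4, viruses_per_group: int = 5,
                   hosts: int = 24,
                   group_host_susceptibility: dict[int, list[str]] | None = None,
                   leak: float = 0.02, lognormal_sigma: float = 0.5,
                   base_titer: float = 1e8, detection_floor: float = 1e3,
                   seed: int = 0) -> tuple[EOPMatrix, SyntheticTruth]:
    """Raw EOP (pfu/mL) matrix generated from adhesin-group susceptibility
    rules with multiplicative lognormal noise and rare off-target leak at
    1e-3 to 1e-6 relative efficiency."""
    rng = np.random.default_rng(seed)
    host_names = [f"H{h + 1:02d}" for h in range(hosts)]
    virus_names = []
    groups: dict[str, int] = {}
    for g in range(1, adhesin_groups + 1):
        for v in range(1, viruses_per_group + 1):
            name = f"VG{g}_{v:02d}"
            virus_names.append(name)
            groups[name] = g
    susceptibility = group_host_susceptibility or default_susceptibility(
        adhesin_groups, host_names)
    for g in range(1, adhesin_groups + 1):
        if g not in susceptibility:
            raise ValueError(f"susceptibility map missing adhesin group {g}")
    values = np.zeros((len(virus_names), hosts))
    isolation: dict[str, str] = {}
    for i, virus in enumerate(virus_names):
        g = groups[virus]
        hosts_g = susceptibility[g]
        if not hosts_g:
            raise ValueError(f"group {g} has no susceptible hosts")
        isolation[virus] = hosts_g[int(rng.integers(0, len(hosts_g)))]
        for j, host in enumerate(host_names):
            if host in hosts_g:
                titer = base_titer * float(np.exp(rng.normal(0.0, lognormal_sigma)))
            elif rng.random() < leak:
                titer = base_titer * 10.0 ** (-float(rng.uniform(3, 6)))
            else:
                titer = 0.0
            values[i, j] = 0.0 if titer <= detection_floor else titer
        # the isolation host must remain detectable
        jh = host_names.index(isolation[virus])
        if values[i, jh] <= detection_floor:
            values[i, jh] = base_titer
    frame = pd.DataFrame(values, index=virus_names, columns=host_names)
    truth = SyntheticTruth(seed=seed, parameters={
        "adhesin_groups": adhesin_groups, "viruses_per_group": viruses_per_group,
        "hosts": hosts, "leak": leak, "lognormal_sigma": lognormal_sigma,
        "base_titer": base_titer, "detection_floor": detection_floor,
    })
    truth.adhesin_groups = groups
    truth.susceptibility = {g: list(h) for g, h in susceptibility.items()}
    return EOPMatrix(frame, isolation, detection_floor=detection_floor), truth


# ---------------------------------------------------------------------------
# Motif-depletion genomes


def _markov_background(rng: np.random.Generator, length: int, gc: float) -> str:
    # independent transitions (a degenerate order-1 chain) keep generation
    # vectorizable; the fitted null is unaffected
    return _dna(rng, length, gc)


def _destroy_occurrence(seq: list[str], pos: int, motif_len: int,
                        rng: np.random.Generator) -> None:
    i = pos + int(rng.integers(0, motif_len))
    old = seq[i]
    choices = "ACGT".replace(old, "")
    seq[i] = choices[rng.integers(0, 3)]


def gen_motif_genomes(n: int = 10, length: int = 40_000, motif: str = "GATC",
                      depletion_factor: float = 1.0, gc: float = DEFAULT_GC,
                      tolerance: float = 0.10, seed: int = 0,
                      id_prefix: str = "M") -> tuple[list[Genome], SyntheticTruth]:
    """Genomes whose observed/expected motif ratio is tuned to
    ``depletion_factor`` (within ``tolerance``, relative) by rejection
    resampling of motif occurrences."""
    if not 0 <= depletion_factor <= 1:
        raise ValueError("depletion_factor must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genomes: list[Genome] = []
    truth = SyntheticTruth(seed=seed, parameters={
        "n": n, "length": length, "motif": motif,
        "depletion_factor": depletion_factor, "gc": gc,
    })
    for i in range(1, n + 1):
        gid = f"{id_prefix}{i:03d}"
        seq = list(_markov_background(rng, length, gc))
        for _ in range(50):
            s = "".join(seq)
            expected = expected_count_markov(s, motif, order=1)
            target = depletion_factor * expected
            count = count_motif(s, motif)
            if depletion_factor == 0:
                if count == 0:
                    break
            elif expected > 0 and abs(count - target) <= tolerance * max(target, 1.0):
                break
            if count > target:
                # destroy a random subset of occurrences
                occ = _motif_positions(s, motif)
                excess = max(1, int(round(count - target)))
                for pos in rng.choice(len(occ), size=min(excess, len(occ)),
                                      replace=False):
                    _destroy_occurrence(seq, occ[int(pos)], len(motif), rng)
            else:
                deficit = max(1, int(round(target - count)))
                for _ in range(deficit):
                    pos = int(rng.integers(0, length - len(motif)))
                    seq[pos : pos + len(motif)] = list(motif.upper())
        genomes.append(Genome(id=gid, sequence="".join(seq),
                              name=f"synthetic motif genome {gid}"))
        truth.depletion_factors[gid] = depletion_factor
    return genomes, truth


def _motif_positions(sequence: str, motif: str) -> list[int]:
    from .motifs import _motif_regex, is_palindromic, motif_revcomp

    positions = [m.start() for m in _motif_regex(motif.upper()).finditer(sequence)]
    if not is_palindromic(motif.upper()):
        positions += [m.start() for m in
                      _motif_regex(motif_revcomp(motif.upper())).finditer(sequence)]
    return sorted(positions)


# ---------------------------------------------------------------------------
# Provirus planting


def plant_provirus(virus: Genome, host_length: int = 200_000, att_len: int = 20,
                   insert_at: int | None = None, gc: float = DEFAULT_GC,
                   host_id: str = "hostA", seed: int = 0,
                   existing_host: Genome | None = None
                   ) -> tuple[Genome, SyntheticTruth]:
    """Insert the virus genome into a (generated or supplied) host contig
    with an ``att_len``-bp direct repeat duplicated at both junctions.

    The three host bases adjacent to each repeat copy are forced to
    mismatch the corresponding virus-side context so that the planted
    repeat is exactly recoverable.
    """
    if existing_host is not None:
        host_seq = existing_host.sequence
        host_id = existing_host.id
        host_length = len(host_seq)
    else:
        rng0 = np.random.default_rng(seed)
        host_seq = _dna(rng0, host_length, gc)
    rng = np.random.default_rng(seed + 1)
    if len(virus.sequence) + 2 * att_len >= host_length:
        raise ValueError("virus genome must be shorter than the host contig")
    if insert_at is None:
        insert_at = int(rng.integers(host_length // 4, 3 * host_length // 4))
    att = _dna(rng, att_len, gc) if att_len > 0 else ""
    pre = list(host_seq[:insert_at])
    post = list(host_seq[insert_at:])
    v = virus.sequence
    if att_len > 0:
        # force mismatching context at all four repeat boundaries
        for k in range(1, 4):
            if len(pre) >= k and len(v) >= k and pre[-k] == v[-k]:
                pre[-k] = "ACGT".replace(v[-k], "")[rng.integers(0, 3)]
            if len(post) >= k and len(v) >= k and post[k - 1] == v[k - 1]:
                post[k - 1] = "ACGT".replace(v[k - 1], "")[rng.integers(0, 3)]
    sequence = "".join(pre) + att + v + att + "".join(post)
    provirus_start = insert_at + att_len
    provirus_end = provirus_start + len(v)
    truth = SyntheticTruth(seed=seed, parameters={
        "host_length": host_length, "att_len": att_len, "virus": virus.id,
    })
    truth.proviruses = [] if existing_host is None else [
        dict(p) for p in getattr(existing_host, "meta", {}).get("proviruses", [])
    ]
    truth.proviruses.append({
        "virus": virus.id, "start": provirus_start, "end": provirus_end,
        "att": att, "att_left_start": insert_at,
        "att_right_start": provirus_end,
    })
    host = Genome(id=host_id, sequence=sequence, name="synthetic host contig",
                  meta={"proviruses": truth.proviruses})
    return host, truth
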