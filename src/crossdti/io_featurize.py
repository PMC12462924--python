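"""Input tables, protein tokenization, molecular graphs, and protein clustering.

Proteins arrive as FASTA or a delimited table, drugs as SMILES strings, and
interactions as (drug_id, protein_id, label[, affinity]) rows.  Proteins are
tokenized over the fixed alphabet A=1..Z=26 (0 reserved for padding; letters
outside the 25 valid amino-acid codes fall back to X), molecules are converted
to heavy-atom graphs with RDKit, and proteins are grouped into sequence
families by k-means over normalized k-mer composition.  Family clusters drive
both the source/target domain split and episode construction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit import RDLogger
from sklearn.cluster import KMeans

RDLogger.DisableLog("rdApp.*")

# 20 canonical residues plus ambiguity/rare codes accepted on input
VALID_AA = set("ACDEFGHIKLMNPQRSTVWYXBZUO")
PAD_TOKEN = 0
DEFAULT_L_MAX = 1200

ELEMENT_LIST = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si"]
MAX_DEGREE = 5
ATOM_FEATURE_DIM = (len(ELEMENT_LIST) + 1) + (MAX_DEGREE + 1) + 1 + 1


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    cluster_id: int | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        self.sequence = "".join(
            c if c in VALID_AA else "X" for c in self.sequence)


@dataclass
class DrugRecord:
    id: str
    smiles: str


@dataclass
class InteractionRecord:
    drug_id: str
    protein_id: str
    label: int
    affinity: float | None = None

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(
                f"interaction ({self.drug_id},{self.protein_id}): "
                f"label must be 0 or 1, got {self.label}")


@dataclass
class TokenizedProtein:
    tokens: np.ndarray  # int array, length L_max, 0-padded suffix
    length: int


@dataclass
class MolecularGraph:
    node_features: np.ndarray  # (num_atoms, ATOM_FEATURE_DIM)
    edges: list[tuple[int, int]]  # undirected, i < j

    @property
    def num_atoms(self) -> int:
        return self.node_features.shape[0]


@dataclass
class ClusterAssignment:
    mapping: dict[str, int]
    n_clusters: int
    feature_kind: str = "kmer_composition"


# ---------------------------------------------------------------------------
# table reading / writing

def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def _read_proteins(path: Path) -> list[ProteinRecord]:
    if path.suffix.lower() in (".fasta", ".fa", ".faa"):
        return [ProteinRecord(id=rec.id, sequence=str(rec.seq))
                for rec in SeqIO.parse(str(path), "fasta")]
    df = _read_table(path)
    return [ProteinRecord(id=r["id"], sequence=r["sequence"])
            for r in df.to_dict("records")]


def read_tables(protein_path, drug_path, interaction_path
                ) -> tuple[list[ProteinRecord], list[DrugRecord],
                           list[InteractionRecord]]:
    """Load the three input tables and cross-validate id references.

    Duplicate (drug, protein) rows with identical labels are collapsed to one;
    rows whose labels conflict are rejected outright, since a pair cannot both
    bind and not bind.
    """
    protein_path, drug_path, interaction_path = (
        Path(protein_path), Path(drug_path), Path(interaction_path))
    for p in (protein_path, drug_path, interaction_path):
        if not p.exists():
            raise FileNotFoundError(str(p))

    proteins = _read_proteins(protein_path)
    drugs = [DrugRecord(id=r["id"], smiles=r["smiles"])
             for r in _read_table(drug_path).to_dict("records")]

    idf = _read_table(interaction_path)
    interactions = []
    for r in idf.to_dict("records"):
        aff = r.get("affinity")
        aff = float(aff) if aff not in (None, "",) and not pd.isna(aff) else None
        interactions.append(InteractionRecord(
            drug_id=r["drug_id"], protein_id=r["protein_id"],
            label=int(r["label"]), affinity=aff))

    pids = {p.id for p in proteins}
    dids = {d.id for d in drugs}
    seen: dict[tuple[str, str], int] = {}
    deduped = []
    for rec in interactions:
        if rec.protein_id not in pids:
            raise KeyError(f"interaction references unknown protein id "
                           f"{rec.protein_id!r}")
        if rec.drug_id not in dids:
            raise KeyError(f"interaction references unknown drug id "
                           f"{rec.drug_id!r}")
        key = (rec.drug_id, rec.protein_id)
        if key in seen:
            if seen[key] != rec.label:
                raise ValueError(f"conflicting duplicate labels for pair {key}")
            continue
        seen[key] = rec.label
        deduped.append(rec)
    return proteins, drugs, deduped


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def write_tables(proteins, drugs, interactions, protein_path, drug_path,
                 interaction_path) -> None:
    """Write the three tables in the formats ``read_tables`` accepts."""
    protein_path = Path(protein_path)
    drug_path, interaction_path = Path(drug_path), Path(interaction_path)
    if protein_path.suffix.lower() in (".fasta", ".fa", ".faa"):
        with open(protein_path, "w") as fh:
            for p in proteins:
                fh.write(f">{p.id}\n{p.sequence}\n")
    else:
        pd.DataFrame({"id": [p.id for p in proteins],
                      "sequence": [p.sequence for p in proteins]}
                     ).to_csv(protein_path, sep=_sep_for(protein_path),
                              index=False)
    pd.DataFrame({"id": [d.id for d in drugs],
                  "smiles": [d.smiles for d in drugs]}
                 ).to_csv(drug_path, sep=_sep_for(drug_path), index=False)
    df = pd.DataFrame({
        "drug_id": [i.drug_id for i in interactions],
        "protein_id": [i.protein_id for i in interactions],
        "label": [i.label for i in interactions]})
    if any(i.affinity is not None for i in interactions):
        df["affinity"] = [i.affinity for i in interactions]
    df.to_csv(interaction_path, sep=_sep_for(interaction_path), index=False)


# ---------------------------------------------------------------------------
# protein tokenization

def tokenize_protein(sequence: str, l_max: int = DEFAULT_L_MAX) -> TokenizedProtein:
    """Map a sequence to integer tokens A=1..Z=26, 0-padded to ``l_max``.

    Characters outside the valid residue codes become X.  Sequences longer
    than ``l_max`` keep their N-terminal prefix.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    sequence = "".join(c if c in VALID_AA else "X" for c in sequence)
    sequence = sequence[:l_max]
    tokens = np.zeros(l_max, dtype=np.int64)
    for i, c in enumerate(sequence):
        tokens[i] = ord(c) - ord("A") + 1
    return TokenizedProtein(tokens=tokens, length=len(sequence))


# ---------------------------------------------------------------------------
# molecular graphs

def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse SMILES into a heavy-atom graph with per-atom feature vectors.

    Features: one-hot element over a fixed list (+ "other"), one-hot heavy
    degree (capped), formal charge, aromaticity flag.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"SMILES with no heavy atoms: {smiles!r}")
    feats = np.zeros((mol.GetNumAtoms(), ATOM_FEATURE_DIM))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        e = ELEMENT_LIST.index(sym) if sym in ELEMENT_LIST else len(ELEMENT_LIST)
        feats[i, e] = 1.0
        deg = min(atom.GetDegree(), MAX_DEGREE)
        feats[i, len(ELEMENT_LIST) + 1 + deg] = 1.0
        feats[i, -2] = float(atom.GetFormalCharge())
        feats[i, -1] = float(atom.GetIsAromatic())
    edges = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
    return MolecularGraph(node_features=feats, edges=sorted(set(edges)))


# ---------------------------------------------------------------------------
# clustering and domain split

def kmer_composition(sequence: str, k: int = 3) -> np.ndarray:
    """Normalized k-mer count vector over the 26-letter alphabet (hashed)."""
    dim = 26 ** k
    v = np.zeros(dim)
    for i in range(len(sequence) - k + 1):
        idx = 0
        for c in sequence[i:i + k]:
            idx = idx * 26 + (ord(c) - ord("A"))
        v[idx] += 1.0
    n = v.sum()
    return v / n if n > 0 else v


def cluster_proteins(proteins: list[ProteinRecord], n_clusters: int,
                     k: int = 3, seed: int = 0) -> ClusterAssignment:
    """Partition proteins into sequence families by k-mer k-means.

    Deterministic for fixed inputs and seed.  Cluster ids are relabelled
    0..n_clusters-1 in order of first appearance so the labelling does not
    depend on k-means internals beyond the partition itself.
    """
    if n_clusters > len({p.sequence for p in proteins}):
        raise ValueError("n_clusters exceeds number of distinct proteins")
    if k < 1:
        raise ValueError("k-mer length must be >= 1")
    # dense 26^k features are fine for k<=3; restrict to observed columns
    X = np.stack([kmer_composition(p.sequence, k) for p in proteins])
    X = X[:, X.any(axis=0)]
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    relabel: dict[int, int] = {}
    mapping = {}
    for p, r in zip(proteins, raw):
        if r not in relabel:
            relabel[r] = len(relabel)
        mapping[p.id] = relabel[r]
    return ClusterAssignment(mapping=mapping, n_clusters=n_clusters)


def split_domains(assignment: ClusterAssignment, target_fraction: float,
                  seed: int = 0) -> tuple[list[int], list[int]]:
    """Hold out whole clusters as the target domain.

    The number of target clusters is round(n_clusters * target_fraction),
    floored at 1; the draw is uniform without replacement under ``seed``.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must lie in (0, 1)")
    n = assignment.n_clusters
    n_target = max(1, round(n * target_fraction))
    if n_target >= n:
        raise ValueError("target_fraction leaves no source clusters")
    rng = np.random.default_rng(seed)
    target = sorted(rng.choice(n, size=n_target, replace=False).tolist())
    source = sorted(set(range(n)) - set(target))
    return source, target


def refine_clusters(assignment: ClusterAssignment, factor: int = 2,
                    seed: int = 0) -> ClusterAssignment:
    """Subdivide each cluster into ``factor`` balanced random subclusters.

    Controls episode granularity: holding out subclusters yields evaluation
    tasks whose proteins are unseen while their broad category was seen —
    the homologous-reference few-shot setting.  A seeded balanced partition
    is used because clusters are internally homogeneous, so a second round
    of composition clustering would only isolate outliers.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    by_cluster: dict[int, list[str]] = {}
    for pid, cid in sorted(assignment.mapping.items()):
        by_cluster.setdefault(cid, []).append(pid)
    mapping: dict[str, int] = {}
    next_id = 0
    for cid in sorted(by_cluster):
        members = by_cluster[cid]
        n_sub = min(factor, len(members))
        order = rng.permutation(len(members))
        for rank, idx in enumerate(order):
            mapping[members[idx]] = next_id + rank % n_sub
        next_id += n_sub
    return ClusterAssignment(mapping=mapping, n_clusters=next_id)


def write_clusters(assignment: ClusterAssignment, path) -> None:
    pd.DataFrame(sorted(assignment.mapping.items()),
                 columns=["protein_id", "cluster_id"]
                 ).to_csv(path, sep="\t", index=False)


def read_clusters(path) -> ClusterAssignment:
    df = pd.read_csv(path, sep="\t")
    mapping = dict(zip(df["protein_id"].astype(str), df["cluster_id"].astype(int)))
    return ClusterAssignment(mapping=mapping,
                             n_clusters=int(df["cluster_id"].max()) + 1)


def drop_redundant(proteins, interactions):
    """Remove exact duplicate sequences and exact duplicate pairs.

    Stand-in for heavier identity-based redundancy filtering: duplicates of a
    sequence keep the first id; interactions are remapped accordingly.
    """
    keep: list[ProteinRecord] = []
    canon: dict[str, str] = {}
    by_seq: dict[str, str] = {}
    for p in proteins:
        if p.sequence in by_seq:
            canon[p.id] = by_seq[p.sequence]
        else:
            by_seq[p.sequence] = p.id
            canon[p.id] = p.id
            keep.append(p)
    seen = set()
    out = []
    for rec in interactions:
        pid = canon.get(rec.protein_id, rec.protein_id)
        key = (rec.drug_id, pid)
        if key in seen:
            continue
        seen.add(key)
        out.append(InteractionRecord(rec.drug_id, pid, rec.label, rec.affinity))
    return keep, out
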