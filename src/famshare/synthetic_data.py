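"""Synthetic cohort generator with household, dog-ownership and age structure.

The generator emulates the design of a cross-sectional family study:
60 households (17 with children only, 17 with dogs only, 8 with both,
18 with neither), each anchored by a cohabiting couple; humans are
sampled at five body sites (feces, tongue, forehead, both palms) and
dogs at seven (feces, tongue, forehead, four paws).

Counts come from a hierarchical Dirichlet-multinomial model:

1. a per-site-group baseline composition (skin baselines concentrated
   on a few dominant skin families, gut and oral baselines on their own
   characteristic families, dog surfaces deliberately flat/even);
2. a per-family, per-site-group profile drawn around the baseline
   (concentration ``kappa_family``; set it to ``inf`` to switch the
   family effect off);
3. a per-individual target composition: couples mix in a shared latent
   draw with weight ``w_sp``; offspring mix the family profile toward
   an infant signature (elevated Streptococcaceae) with weight
   ``exp(-age / age_tau)``; human skin sites in dog-owning households
   mix in a rare-taxon dog-surface profile with weight ``w_dog``;
4. an individual profile drawn around the target (``kappa_individual``)
   and multinomial counts at a lognormal sequencing depth.

Every draw is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import OtuTable, SampleMetadata, HUMAN_SITES, DOG_SITES

__all__ = ["SimulationConfig", "simulate_tree", "simulate_households",
           "simulate_counts", "simulate_dataset", "TAXON_FAMILY_POOL"]

#: bacterial family labels used for simulated taxonomy strings (drawn from
#: lineages commonly reported for human/dog skin, oral and gut communities)
TAXON_FAMILY_POOL = (
    "Propionibacteriaceae", "Streptococcaceae", "Staphylococcaceae",
    "Corynebacteriaceae", "Micrococcaceae", "Prevotellaceae",
    "Porphyromonadaceae", "Flavobacteriaceae", "Bacteroidaceae",
    "Carnobacteriaceae", "Veillonellaceae", "Lachnospiraceae",
    "Ruminococcaceae", "Fusobacteriaceae", "Sphingomonadaceae",
    "Neisseriaceae", "Comamonadaceae", "Pasteurellaceae", "Moraxellaceae",
    "Pseudomonadaceae", "Enterobacteriaceae", "Microbacteriaceae",
    "Nocardioidaceae", "Hyphomicrobiaceae", "Methylophilaceae",
)

_SKIN_FAMILIES = ("Propionibacteriaceae", "Streptococcaceae", "Staphylococcaceae")
_GUT_FAMILIES = ("Bacteroidaceae", "Lachnospiraceae", "Ruminococcaceae",
                 "Enterobacteriaceae")
_ORAL_FAMILIES = ("Streptococcaceae", "Prevotellaceae", "Veillonellaceae",
                  "Neisseriaceae", "Pasteurellaceae")

#: internal site groups: samples in one group share baselines/profiles
_SITE_GROUPS = {
    ("human", "fecal"): "human_gut",
    ("human", "oral"): "human_oral",
    ("human", "forehead"): "human_skin",
    ("human", "palm_L"): "human_skin",
    ("human", "palm_R"): "human_skin",
    ("dog", "fecal"): "dog_gut",
    ("dog", "oral"): "dog_oral",
    ("dog", "forehead"): "dog_skin",
    ("dog", "paw_BL"): "dog_skin",
    ("dog", "paw_BR"): "dog_skin",
    ("dog", "paw_FL"): "dog_skin",
    ("dog", "paw_FR"): "dog_skin",
}

_HUMAN_SKIN_SITES = ("forehead", "palm_L", "palm_R")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study design being emulated: 17/17/8/18
    households with children/dogs/both/neither, lognormal depths around
    20,000 reads, moderate family- and couple-level sharing, a dog
    effect confined to human skin, and a strong infant signature that
    decays with age (time constant ``age_tau`` years).
    """

    n_families_by_type: tuple[int, int, int, int] = (17, 17, 8, 18)
    n_taxa: int = 500
    n_taxon_families: int = 25
    depth_meanlog: float = math.log(20000.0)
    depth_sdlog: float = 0.6
    kappa_site: float = 50.0
    kappa_family: float = 30.0       # math.inf disables the family effect
    kappa_spouse: float = 30.0       # concentration of the couple-shared draw
    kappa_individual: float = 200.0
    w_sp: float = 0.35               # couple shared-draw mixing weight
    w_pc: float = 0.2                # parent-child mixing weight
    w_dog: float = 0.15              # dog -> human-skin mixing weight
    age_tau: float = 1.5             # years; decay of the infant signature
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_families_by_type) != 4 or any(n < 0 for n in self.n_families_by_type):
            raise ValueError("n_families_by_type must be 4 non-negative counts")
        for name in ("kappa_site", "kappa_family", "kappa_spouse", "kappa_individual"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("w_sp", "w_pc", "w_dog"):
            w = getattr(self, name)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.age_tau <= 0:
            raise ValueError("age_tau must be > 0")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_taxon_families < 1 or self.n_taxon_families > len(TAXON_FAMILY_POOL):
            raise ValueError(
                f"n_taxon_families must be in [1, {len(TAXON_FAMILY_POOL)}]")

    def null(self) -> "SimulationConfig":
        """No family, couple, parent-child or dog effect (type-I calibration)."""
        return replace(self, kappa_family=math.inf, w_sp=0.0, w_pc=0.0, w_dog=0.0)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int, branch_mean: float = 0.1) -> TreeNode:
    """Random rooted bifurcating tree by iterative pair-joining.

    Tips are labeled ``OTU_1..OTU_n``; branch lengths are i.i.d.
    Exponential with mean ``branch_mean``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng([seed, 0x7EE])
    nodes = [TreeNode(name=f"OTU_{i + 1}", length=float(rng.exponential(branch_mean)))
             for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b],
                          length=float(rng.exponential(branch_mean)))
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def taxonomy_strings(n_taxa: int, n_taxon_families: int) -> list[str]:
    """Round-robin assignment of OTUs to family-rank lineage strings."""
    fams = TAXON_FAMILY_POOL[:n_taxon_families]
    out = []
    for i in range(n_taxa):
        fam = fams[i % len(fams)]
        out.append("k__Bacteria; p__; c__; o__; f__" + fam + "; g__; s__")
    return out


# ---------------------------------------------------------------------------
# Households / metadata
# ---------------------------------------------------------------------------

def simulate_households(config: SimulationConfig) -> SampleMetadata:
    """Family rosters and one metadata record per physical sample.

    Every family has one adult couple (``adult_M`` + ``adult_F``, ages
    26-55 y); children-type families carry 1-3 offspring with ages
    Uniform(0.5, 18) (role ``infant`` below 1 y); dog-type families
    carry 1-2 dogs; "both" families carry both.  Humans get 5 sample
    records, dogs 7.
    """
    rng = np.random.default_rng([config.seed, 0xFA41])
    n_child, n_dog, n_both, n_neither = config.n_families_by_type
    types = (["children"] * n_child + ["dogs"] * n_dog
             + ["both"] * n_both + ["neither"] * n_neither)
    records = []

    def add_host(fam: str, host: str, species: str, role: str, age: float,
                 has_dog: bool, has_cat: bool, size: int) -> None:
        sites = HUMAN_SITES if species == "human" else DOG_SITES
        for site in sites:
            records.append({
                "sample_id": f"{host}.{site}",
                "host_id": host, "family_id": fam, "body_site": site,
                "species": species, "role": role, "age": round(age, 3),
                "has_dog": has_dog, "has_cat": has_cat, "family_size": size,
            })

    for f, ftype in enumerate(types, start=1):
        fam = f"F{f:03d}"
        with_children = ftype in ("children", "both")
        with_dogs = ftype in ("dogs", "both")
        kids = int(rng.integers(1, 4)) if with_children else 0
        dogs = int(rng.integers(1, 3)) if with_dogs else 0
        size = 2 + kids
        has_cat = bool(rng.random() < 0.3)
        members = []
        for role in ("adult_M", "adult_F"):
            members.append((f"{fam}.{role}", "human", role,
                            float(rng.uniform(26.0, 55.0))))
        for k in range(kids):
            age = float(rng.uniform(0.5, 18.0))
            role = "infant" if age < 1.0 else "child"
            members.append((f"{fam}.K{k + 1}", "human", role, age))
        for d in range(dogs):
            members.append((f"{fam}.D{d + 1}", "dog", "dog",
                            float(rng.uniform(1.0, 12.0))))
        for host, species, role, age in members:
            add_host(fam, host, species, role, age, with_dogs, has_cat, size)

    df = pd.DataFrame.from_records(records).set_index("sample_id")
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _baseline_weights(group: str, tax_families: list[str], rng) -> np.ndarray:
    """Sparse-ish prior weight vector for one site group."""
    n = len(tax_families)
    w = np.full(n, 0.2)
    if group == "human_skin":
        heavy = _SKIN_FAMILIES
    elif group == "human_gut":
        heavy = _GUT_FAMILIES
    elif group == "human_oral":
        heavy = _ORAL_FAMILIES
    else:
        heavy = ()                 # dog surfaces & gut: flat, even profile
    for i, fam in enumerate(tax_families):
        if fam in heavy:
            w[i] = 4.0
        if group.startswith("dog"):
            w[i] = 1.0
    return w / w.sum()


def simulate_counts(metadata: SampleMetadata, tree: TreeNode,
                    config: SimulationConfig) -> OtuTable:
    """Draw the hierarchical Dirichlet-multinomial count table.

    See the module docstring for the four-level generative model.
    """
    rng = np.random.default_rng([config.seed, 0xC0117])
    otu_ids = [f"OTU_{i + 1}" for i in range(config.n_taxa)]
    tip_names = {t.name for t in tree.tips()}
    if not set(otu_ids) <= tip_names:
        raise ValueError("tree tips do not cover the configured taxa")
    taxonomy = taxonomy_strings(config.n_taxa, config.n_taxon_families)
    tax_families = [t.split("f__")[1].split(";")[0] for t in taxonomy]

    groups = sorted(set(_SITE_GROUPS.values()))
    beta = {}
    for g in groups:
        w = _baseline_weights(g, tax_families, rng)
        # dog surfaces get a 10x concentration so their baselines come out
        # flat and even compared with the dominated human skin profile
        kappa = config.kappa_site * (10.0 if g.startswith("dog") else 1.0)
        beta[g] = rng.dirichlet(kappa * w)

    # infant signature: half the mass on Streptococcaceae-labeled taxa
    strep = np.array([f == "Streptococcaceae" for f in tax_families], dtype=float)
    iota = {}
    for g in ("human_gut", "human_oral", "human_skin"):
        iota[g] = 0.5 * strep / strep.sum() + 0.5 * beta[g]

    fams = metadata.families()
    hosts = metadata.hosts()

    def family_profile(g: str) -> dict[str, np.ndarray]:
        if math.isinf(config.kappa_family):
            return {fam: beta[g] for fam in fams}
        return {fam: rng.dirichlet(config.kappa_family * beta[g]) for fam in fams}

    phi = {g: family_profile(g) for g in groups}
    # couple-shared latent draw, one per family x human site group
    psi = {g: {fam: rng.dirichlet(config.kappa_spouse * beta[g]) for fam in fams}
           for g in ("human_gut", "human_oral", "human_skin")}

    # rare-taxon dog-surface donor profile per dog-owning family: the
    # family's dog_skin profile restricted to taxa rare in the human skin
    # baseline (below-median baseline mass)
    rare_mask = beta["human_skin"] < np.median(beta["human_skin"])
    dog_donor = {}
    for fam in fams:
        donor = phi["dog_skin"][fam] * rare_mask
        total = donor.sum()
        dog_donor[fam] = donor / total if total > 0 else beta["dog_skin"]

    # per-host, per-site-group target compositions
    targets: dict[tuple[str, str], np.ndarray] = {}
    for host, row in hosts.iterrows():
        fam, role, species = row["family_id"], row["role"], row["species"]
        host_groups = ("dog_gut", "dog_oral", "dog_skin") if species == "dog" \
            else ("human_gut", "human_oral", "human_skin")
        for g in host_groups:
            base = phi[g][fam]
            if species == "dog":
                target = base
            elif role in ("adult_M", "adult_F", "senior"):
                target = (1.0 - config.w_sp) * base + config.w_sp * psi[g][fam]
            else:  # child / infant
                a = math.exp(-float(row["age"]) / config.age_tau)
                child_base = (1.0 - config.w_pc) * base + config.w_pc * psi[g][fam]
                target = (1.0 - a) * child_base + a * iota[g]
            if (species == "human" and g == "human_skin"
                    and bool(row["has_dog"]) and config.w_dog > 0):
                target = (1.0 - config.w_dog) * target + config.w_dog * dog_donor[fam]
            targets[(host, g)] = target

    counts = np.zeros((config.n_taxa, len(metadata)), dtype=np.int64)
    frame = metadata.frame
    for j, (sid, row) in enumerate(frame.iterrows()):
        g = _SITE_GROUPS[(row["species"], row["body_site"])]
        target = targets[(row["host_id"], g)]
        profile = rng.dirichlet(config.kappa_individual * target)
        if config.depth_sdlog == 0.0:
            depth = max(1, int(round(math.exp(config.depth_meanlog))))
        else:
            depth = max(1, int(round(float(
                rng.lognormal(config.depth_meanlog, config.depth_sdlog)))))
        counts[:, j] = rng.multinomial(depth, profile)
    return OtuTable(otu_ids, list(frame.index), counts, taxonomy)


def simulate_dataset(config: SimulationConfig):
    """Convenience: (table, tree, metadata) for one seeded cohort."""
    tree = simulate_tree(config.n_taxa, config.seed)
    metadata = simulate_households(config)
    table = simulate_counts(metadata, tree, config)
    return table, tree, metadata
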