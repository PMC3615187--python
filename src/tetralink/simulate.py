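"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates a survey of geothermal springs spanning acidic to
alkaline pH:

* spring chemistry with the field's characteristic covariances (ammonium
  and ferrous iron enriched in acidic springs, nitrite in alkaline ones);
* core and polar tetraether lipid compositions whose mean ring number
  declines linearly with pH, drawn on the simplex from a Dirichlet so
  the >=0 / sum-to-100 invariants hold by construction, with crenarchaeol
  allocated increasingly toward alkaline springs;
* an ultrametric pure-birth OTU phylogeny whose tips carry pH optima
  evolved by Brownian motion (tunable phylogenetic signal), and site
  communities assembled by Gaussian pH niche filtering on those optima;
* qPCR-style gene-abundance tables in which archaeal amoA tracks the
  product of a designated carrier OTU's abundance and crenarchaeol
  concentration.

Every output is a pure function of (config, seed).  Defaults describe
the emulated study's conditions (27 springs, pH 2-9.6, ring index falling
~0.35 rings per pH unit, 31 OTUs) and are documented in docs/methods.md.
"""

from __future__ import annotations

import math
import random
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .errors import ConfigurationError
from .geochem import ANALYTES, SpringGeochem
from .lipids import SPECIES_CODES, LipidProfile
from .phylo import CommunityTable, Phylogeny

__all__ = [
    "SimConfig",
    "gen_springs",
    "gen_lipids",
    "gen_tree_communities",
    "gen_gene_abundances",
    "write_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic survey.

    Units: pH ranges in pH units, temperature in deg C, ``ri_intercept``
    in rings, ``ri_slope`` in rings per pH unit (negative: acidic springs
    carry more rings), ``ri_noise_sd`` in rings, ``signal_sd`` is the
    Brownian rate (trait SD per unit tree height) of the tip pH optima,
    ``niche_breadth`` in pH units.
    """

    n_springs: int = 27
    ph_range: tuple[float, float] = (2.0, 9.6)
    temp_range: tuple[float, float] = (16.0, 87.0)
    ri_intercept: float = 5.2
    ri_slope: float = -0.35
    ri_noise_sd: float = 0.25
    dirichlet_concentration: float = 200.0
    core_polar_coupling: float = 0.85
    n_otus: int = 31
    signal_sd: float = 1.5
    niche_breadth: float = 1.0
    amoa_link_strength: float = 1.0
    #: Steepness of the crenarchaeol-vs-pH allocation; 0 makes the
    #: crenarchaeol share of the five-ring mass independent of pH.
    cren_ph_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ph_range[0] >= self.ph_range[1]:
            raise ConfigurationError("ph_range must be (low, high) with low < high")
        if self.temp_range[0] >= self.temp_range[1]:
            raise ConfigurationError("temp_range must be (low, high)")
        for name in (
            "ri_noise_sd",
            "dirichlet_concentration",
            "signal_sd",
            "niche_breadth",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0.0 <= self.core_polar_coupling < 1.0:
            raise ConfigurationError("core_polar_coupling must be in [0, 1)")
        if self.amoa_link_strength < 0:
            raise ConfigurationError("amoa_link_strength must be >= 0")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    # One independent, order-insensitive stream per generator stage.
    return np.random.default_rng([cfg.seed, zlib.crc32(stream.encode())])


def _spring_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def gen_springs(cfg: SimConfig) -> list[SpringGeochem]:
    """Simulate spring geochemistry records.

    pH and temperature are independent uniforms on their ranges.  On the
    log scale, ammonium and ferrous iron decline with pH and nitrite
    rises, each with lognormal noise sized so the population pH-ammonium
    correlation sits near -0.6; the remaining analytes are independent
    lognormals at field-plausible scales.
    """
    if cfg.n_springs < 3:
        raise ConfigurationError("n_springs must be >= 3")
    rng = _rng(cfg, "springs")
    n = cfg.n_springs
    ph = rng.uniform(*cfg.ph_range, size=n)
    temp = rng.uniform(*cfg.temp_range, size=n)

    def logn(mu: np.ndarray | float, sd: float) -> np.ndarray:
        return np.exp(np.asarray(mu, dtype=float) + rng.normal(0.0, sd, size=n))

    analytes = {
        "nh4": logn(6.0 - 0.35 * ph, 1.0),  # uM, enriched when acidic
        "no2": logn(3.0 + 0.35 * ph, 1.0),  # nM, enriched when alkaline
        "fe2": logn(2.5 - 0.30 * ph, 1.0),  # uM, enriched when acidic
        "no3": logn(6.0, 1.0),  # nM
        "sulfide": logn(1.0, 1.2),  # uM
        "conductivity": logn(8.0, 0.5),  # umhos/cm
        "salinity": logn(0.5, 0.6),  # percent
        "cl": logn(1.5, 0.8),  # mM
        "so4": logn(0.3, 0.8),  # mM
    }
    records = []
    for i, sid in enumerate(_spring_ids(n)):
        values: dict[str, float | None] = {
            "ph": float(ph[i]),
            "temp": float(temp[i]),
        }
        for a in ANALYTES:
            values[a] = float(analytes[a][i])
        records.append(SpringGeochem(spring_id=sid, values=values))
    return records


# Share of each ring-weight class routed to specific species.  Weight 0 is
# split between GTGT-0 and GDGT-0; weights 4 and 5 between the parent and
# its regioisomer; the crenarchaeol share of weight-5 mass grows with pH.
_ISOMER_SHARE = 0.08


def _mean_composition(
    target_ri: float, ph: float, cren_strength: float = 1.0
) -> np.ndarray:
    rings = np.arange(9, dtype=float)
    mass = np.exp(-((rings - target_ri) ** 2) / (2 * 1.1**2))
    mass /= mass.sum()
    cren_share = 0.5 / (1.0 + math.exp(-cren_strength * (ph - 6.5) / 1.2))
    mean = dict.fromkeys(SPECIES_CODES, 0.0)
    mean["GTGT-0"] = 0.10 * mass[0]
    mean["GDGT-0"] = 0.90 * mass[0]
    for r in (1, 2, 3, 6, 7, 8):
        mean[f"GDGT-{r}"] = mass[r]
    mean["GDGT-4"] = (1 - _ISOMER_SHARE) * mass[4]
    mean["GDGT-4p"] = _ISOMER_SHARE * mass[4]
    m5 = mass[5]
    mean["CREN"] = cren_share * 0.9 * m5
    mean["CREN-ISO"] = cren_share * 0.1 * m5
    mean["GDGT-5"] = (1 - cren_share) * (1 - _ISOMER_SHARE) * m5
    mean["GDGT-5p"] = (1 - cren_share) * _ISOMER_SHARE * m5
    vec = np.array([mean[c] for c in SPECIES_CODES])
    return vec / vec.sum()


def gen_lipids(
    springs: Sequence[SpringGeochem], cfg: SimConfig
) -> tuple[list[LipidProfile], list[LipidProfile]]:
    """Simulate coupled core and polar lipid profiles for each spring.

    The per-spring target ring index is ``ri_intercept + ri_slope * pH``
    plus Gaussian noise, clipped to [0, 8]; the mean composition spreads
    that target over ring-weight classes as a discretised unimodal
    profile, and the realised core composition is a Dirichlet draw around
    it.  The polar composition is a fresh Dirichlet draw centred on the
    realised core composition, with concentration set by
    ``core_polar_coupling`` (coupling -> 1 collapses polar onto core).
    """
    if not springs:
        raise ConfigurationError("springs must be non-empty")
    rng = _rng(cfg, "lipids")
    conc = cfg.dirichlet_concentration
    kappa = conc * cfg.core_polar_coupling / (1.0 - cfg.core_polar_coupling)
    core: list[LipidProfile] = []
    polar: list[LipidProfile] = []
    for rec in springs:
        ph = rec.values["ph"]
        assert ph is not None
        target = cfg.ri_intercept + cfg.ri_slope * ph
        target += rng.normal(0.0, cfg.ri_noise_sd)
        target = float(np.clip(target, 0.0, 8.0))
        mean = _mean_composition(target, ph, cfg.cren_ph_strength)
        core_p = rng.dirichlet(conc * mean)
        polar_p = rng.dirichlet(kappa * core_p + 1e-6)
        core_total = float(np.exp(rng.normal(7.5, 1.5)))
        polar_total = core_total * float(np.exp(rng.normal(-1.2, 1.0)))
        arch_c = core_total * float(np.exp(rng.normal(-4.0, 0.8)))
        arch_p = polar_total * float(np.exp(rng.normal(-4.0, 0.8)))
        core.append(
            LipidProfile(
                spring_id=rec.spring_id,
                fraction="core",
                rel_abundance=dict(zip(SPECIES_CODES, 100.0 * core_p)),
                total_igdgt=core_total,
                archaeol=arch_c,
            )
        )
        polar.append(
            LipidProfile(
                spring_id=rec.spring_id,
                fraction="polar",
                rel_abundance=dict(zip(SPECIES_CODES, 100.0 * polar_p)),
                total_igdgt=polar_total,
                archaeol=arch_p,
            )
        )
    return core, polar


def _brownian_tip_values(
    tree: dendropy.Tree, rate_sd: float, rng: np.random.Generator
) -> dict[str, float]:
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        el = node.edge.length or 0.0
        values[id(node)] = parent + rng.normal(0.0, rate_sd * math.sqrt(el))
    return {
        leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()
    }


def gen_tree_communities(
    springs: Sequence[SpringGeochem], cfg: SimConfig
) -> tuple[Phylogeny, CommunityTable]:
    """Simulate an OTU phylogeny and pH-filtered site communities.

    A pure-birth tree with ``n_otus`` tips is rescaled to unit height
    (hence ultrametric).  Tip pH optima evolve by Brownian motion at rate
    ``signal_sd`` and are mapped affinely onto ``ph_range``, preserving
    the phylogenetic signal.  The abundance of OTU i at spring k is
    proportional to a Gaussian kernel in ``|pH_k - optimum_i|`` with SD
    ``niche_breadth``; ``niche_breadth = inf`` disables filtering and all
    communities are identical.
    """
    if cfg.n_otus < 4:
        raise ConfigurationError("n_otus must be >= 4")
    rng = _rng(cfg, "tree")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=cfg.n_otus,
        rng=random.Random(int(rng.integers(2**31))),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU{i + 1:02d}"
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    height = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height

    raw = _brownian_tip_values(tree, cfg.signal_sd, rng)
    labels = sorted(raw)
    z = np.array([raw[t] for t in labels])
    lo, hi = cfg.ph_range
    if np.ptp(z) < 1e-12:
        optima = np.full(len(z), (lo + hi) / 2.0)
    else:
        optima = lo + (z - z.min()) / np.ptp(z) * (hi - lo)

    ph = np.array([r.values["ph"] for r in springs], dtype=float)
    if math.isinf(cfg.niche_breadth):
        weights = np.ones((len(ph), len(labels)))
    else:
        weights = np.exp(
            -((ph[:, None] - optima[None, :]) ** 2)
            / (2.0 * cfg.niche_breadth**2)
        )
        weights += 1e-12  # guard against all-zero rows at extreme pH
    table = pd.DataFrame(
        weights / weights.sum(axis=1, keepdims=True),
        index=pd.Index([r.spring_id for r in springs], name="site"),
        columns=labels,
    )
    return Phylogeny(tree=tree), CommunityTable(p=table)


def gen_gene_abundances(
    phylogeny: Phylogeny,
    community: CommunityTable,
    lipids: Sequence[LipidProfile],
    cfg: SimConfig,
    carrier: str | None = None,
) -> pd.DataFrame:
    """Simulate qPCR-style gene abundances (copies per ng DNA) per site.

    One OTU — by default the deepest tip, ties broken by label — carries
    archaeal amoA; its expected abundance is ``amoa_link_strength`` times
    the product of the carrier's relative abundance and the crenarchaeol
    concentration in the supplied lipid fraction, with lognormal noise.
    16S copies follow total lipid concentration as a biomass proxy.
    Returns a tidy frame (site, gene, copies).
    """
    rng = _rng(cfg, "genes")
    if carrier is None:
        depths = phylogeny.root_distances()
        carrier = min(depths, key=lambda t: (-depths[t], t))
    if carrier not in community.otus:
        raise ConfigurationError(f"carrier OTU {carrier!r} not in community table")
    by_id = {p.spring_id: p for p in lipids}
    rows = []
    for site in community.sites:
        prof = by_id.get(site)
        if prof is None:
            continue
        cren = prof.rel_abundance.get("CREN", 0.0) / 100.0 * prof.total_igdgt
        carrier_ab = float(community.p.loc[site, carrier])
        # Multiplicative lognormal noise on the link term, plus a lognormal
        # baseline so zero-link sites still yield detectable copies.
        amoa = cfg.amoa_link_strength * carrier_ab * cren * math.exp(
            rng.normal(0.0, 0.3)
        ) + math.exp(rng.normal(0.0, 0.5))
        ssu = prof.total_igdgt * math.exp(rng.normal(0.0, 0.5))
        rows.append({"site": site, "gene": "amoA", "copies": amoa})
        rows.append({"site": site, "gene": "16S", "copies": ssu})
    return pd.DataFrame(rows, columns=["site", "gene", "copies"])


def write_dataset(out_dir: str | Path, cfg: SimConfig) -> dict[str, Path]:
    """Generate one complete dataset and write it as TSV/newick files.

    Emits the same formats the parsers read, plus the generating
    configuration, and returns the path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    springs = gen_springs(cfg)
    core, polar = gen_lipids(springs, cfg)
    tree, comm = gen_tree_communities(springs, cfg)
    genes = gen_gene_abundances(tree, comm, polar, cfg)

    paths: dict[str, Path] = {}

    geo_rows = []
    from .geochem import VARIABLES

    for r in springs:
        geo_rows.append(
            [r.spring_id] + [r.values[v] for v in VARIABLES]
        )
    geo = pd.DataFrame(geo_rows, columns=["spring_id", *VARIABLES])
    paths["geochem"] = out / "geochem.tsv"
    geo.to_csv(paths["geochem"], sep="\t", index=False, float_format="%.6g")

    for name, profiles in (("core_lipids", core), ("polar_lipids", polar)):
        rows = []
        for p in profiles:
            rows.append(
                [p.spring_id]
                + [p.rel_abundance[c] for c in SPECIES_CODES]
                + [p.total_igdgt, p.archaeol]
            )
        frame = pd.DataFrame(
            rows,
            columns=["spring_id", *SPECIES_CODES, "total_igdgt", "archaeol"],
        )
        paths[name] = out / f"{name}.tsv"
        frame.to_csv(paths[name], sep="\t", index=False, float_format="%.6g")

    paths["tree"] = out / "tree.nwk"
    tree.write(paths["tree"])
    paths["communities"] = out / "communities.tsv"
    comm.to_tsv(paths["communities"])
    paths["genes"] = out / "genes.tsv"
    genes.to_csv(paths["genes"], sep="\t", index=False, float_format="%.6g")

    paths["config"] = out / "sim_config.json"
    cfg_dict = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(cfg).items()
    }
    paths["config"].write_text(
        pd.Series(cfg_dict).to_json(indent=2) + "\n"
    )
    return paths


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Config identical to ``cfg`` but with a different seed."""
    return replace(cfg, seed=seed)
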