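"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume:
constant-rate birth-death trees conditioned on tip count; forward (Gillespie)
DEC range histories with epoch-specific dispersal multipliers and a full
event log; climate grids with a latitudinal temperature gradient, a
low-latitude arid precipitation belt and seeded noise; and occurrence
tables drawn from Gaussian climatic niches in (MAT, MAP). Everything is
bit-reproducible under a fixed seed.

A deterministic "survey-mimic" occurrence fixture ships as code: 65 raw
specimen rows that collapse to 54 summarized occurrences (24 pterosaur,
30 lagerpetid) with 8 two-stage records and climate-analysis groups of
23 / 9 / 17 — the counts a published compilation of Triassic pterosauromorph
occurrences produces under the same filters — so count-sensitive behaviour
is testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .areas import AreaScheme
from .climate import ClimateGrid
from .dec import BiogeoParams, EpochSchedule, cladogenesis_table
from .occurrences import DEFAULT_STAGES, OccurrenceRecord, StageTable
from .statespace import RangeStateSpace
from .trees import TimeCalibratedTree, _from_nested

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "DECHistory",
    "simulate_dec_history",
    "generate_climate_grid",
    "generate_climate_stack",
    "sample_occurrences",
    "triassic_survey_occurrences",
    "triassic_survey_grids",
    "area5_from_coords",
    "area8_from_coords",
]


@dataclass
class SimulationConfig:
    """One block of knobs for every generator.

    Climate defaults sketch a greenhouse world: warm poles, ~32 degC at the
    equator with a 0.45 degC/deg latitudinal gradient, wet baseline
    precipitation with a 900 mm trough over a southern subtropical arid
    band. Niche truths give lagerpetids a warm/dry preference and
    pterosaurs a cooler/wetter one.
    """

    seed: int = 0
    # birth-death tree
    birth_rate: float = 0.15          # per Myr
    death_rate: float = 0.05          # per Myr
    n_tips: int = 150
    # DEC truth
    dec_d: float = 0.02               # per area pair per Myr
    dec_e: float = 0.01               # per area per Myr
    dec_j: float = 0.0
    # climate fields
    grid_spacing_deg: float = 2.0
    equator_mat_c: float = 32.0
    mat_gradient_c_per_deg: float = 0.45
    mat_noise_sd: float = 1.0
    map_base_mm: float = 1400.0
    arid_band: tuple = (-30.0, -10.0)
    arid_trough_mm: float = 900.0
    map_noise_sd: float = 50.0
    tseas_base_c: float = 2.0
    tseas_gradient_c_per_deg: float = 0.35
    tseas_noise_sd: float = 0.5
    pseas_base_mm: float = 60.0
    pseas_noise_sd: float = 5.0
    land_fraction: float = 0.45
    # Gaussian climatic niches per clade: (MAT mean, MAT sd, MAP mean, MAP sd)
    niche_truth: dict = field(default_factory=lambda: {
        "lagerpetid": (30.0, 4.0, 800.0, 300.0),
        "pterosaur": (24.0, 3.0, 1400.0, 250.0),
    })

    def __post_init__(self):
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        for sd in (self.mat_noise_sd, self.map_noise_sd, self.tseas_noise_sd,
                   self.pseas_noise_sd):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")
        for clade, (m, ms, p, ps) in self.niche_truth.items():
            if ms <= 0 or ps <= 0:
                raise ValueError(f"niche SDs for {clade} must be > 0")


# ---------------------------------------------------------------------------
# birth-death trees


def simulate_tree(config: SimulationConfig, rng: np.random.Generator | None = None
                  ) -> TimeCalibratedTree:
    """Constant-rate birth-death tree conditioned on the extant tip count.

    The process runs forward until the target count is first reached, then
    for one further waiting time (so it would change at the next event);
    extinct lineages are pruned. Lineages that die out entirely are
    resampled, up to 100 attempts.
    """
    if config.n_tips < 2:
        raise ValueError("need at least 2 tips")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam, mu, n = config.birth_rate, config.death_rate, config.n_tips
    for _attempt in range(100):
        nested = _grow_bd(rng, lam, mu, n)
        if nested is not None:
            return _from_nested(nested)
    raise RuntimeError("all lineages went extinct in 100 attempts")


def _grow_bd(rng, lam, mu, n_target):
    # node: [split_time or None, parent_idx, alive]
    t = 0.0
    # active lineages: list of dict(start=t, children placeholder)
    class L:  # noqa: N801 - tiny record
        __slots__ = ("start", "end", "kids")

        def __init__(self, start):
            self.start = start
            self.end = None
            self.kids = None

    root = L(0.0)
    active = [root]
    while True:
        k = len(active)
        if k == 0:
            return None
        rate = (lam + mu) * k
        t += rng.exponential(1.0 / rate)
        if k == n_target:
            # cut just before this event: present day is t
            break
        who = int(rng.integers(k))
        lin = active.pop(who)
        lin.end = t
        if rng.random() < lam / (lam + mu):
            lin.kids = (L(t), L(t))
            active.extend(lin.kids)
        # else: death, no children
    present = t
    for lin in active:
        lin.end = present

    # prune extinct, suppress unifurcations, relabel extant tips
    counter = [0]

    def build(lin):
        if lin.kids is None:
            if lin.end < present:  # extinct
                return None
            label = f"t{counter[0]}"
            counter[0] += 1
            return (label, 0.0, [])
        sub = [build(c) for c in lin.kids]
        sub = [s for s in sub if s is not None]
        if not sub:
            return None
        if len(sub) == 1:
            return sub[0]
        return (None, present - lin.end, sub)

    nested = build(root)
    if nested is None or not nested[2]:
        return None
    # count tips
    def ntips(nd):
        return 1 if not nd[2] else sum(ntips(c) for c in nd[2])

    if ntips(nested) != n_target:
        return None
    return nested


# ---------------------------------------------------------------------------
# forward DEC simulation


@dataclass
class DECHistory:
    """Ground truth of one forward DEC simulation."""

    tip_ranges: dict            # tip label -> tuple of area labels
    node_states: np.ndarray     # node id -> state index
    branch_events: list         # dicts: branch child id, age, kind, area, from/to state
    clado_events: list          # dicts: node id, age, parent/left/right states

    def node_marginals(self, space: RangeStateSpace) -> np.ndarray:
        m = np.zeros((len(self.node_states), space.n_states))
        m[np.arange(len(self.node_states)), self.node_states] = 1.0
        return m


def simulate_dec_history(
    tree: TimeCalibratedTree,
    params: BiogeoParams,
    space: RangeStateSpace,
    schedule: EpochSchedule | None = None,
    rng: np.random.Generator | None = None,
    root_state: int | None = None,
    max_attempts: int = 100,
) -> DECHistory:
    """Gillespie simulation of range evolution along the tree.

    Anagenesis runs piecewise between epoch boundaries; cladogenesis draws
    from the model's normalized event table. Histories in which any tip
    ends with the null range are resampled from the root (the observable
    data condition on range survival), up to ``max_attempts``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    schedule = schedule or EpochSchedule.free(space.k)
    clado = cladogenesis_table(space, params).as_dict()
    singletons = [i for i, s in enumerate(space.states) if len(s) == 1]
    idx = {s: i for i, s in enumerate(space.states)}
    for _attempt in range(max_attempts):
        start = root_state if root_state is not None else int(rng.choice(singletons))
        out = _run_history(tree, params, space, schedule, clado, idx, rng, start)
        if out is not None:
            return out
    raise RuntimeError(f"range died out in every one of {max_attempts} attempts")


def _run_history(tree, params, space, schedule, clado, idx, rng, root_state):
    n = tree.n_nodes
    node_states = np.full(n, -1, dtype=int)
    branch_events, clado_events = [], []
    root = tree.root
    node_states[root] = root_state
    order = tree.postorder()[::-1]  # preorder
    for v in order:
        kids = tree.children[v]
        if not kids:
            continue
        state = int(node_states[v])
        if len(kids) == 1:
            child_states = [state]
        else:
            events = clado.get(state)
            if not events:
                return None
            probs = np.array([w for _, _, w in events])
            pick = events[int(rng.choice(len(events), p=probs / probs.sum()))]
            child_states = [pick[0], pick[1]]
            clado_events.append({
                "node": v, "age": float(tree.ages[v]), "parent_state": state,
                "left_state": pick[0], "right_state": pick[1],
            })
        for c, s0 in zip(kids, child_states):
            # condition each branch on range survival: a path ending in the
            # null range is marked extinct-in-range and redrawn
            s_end = 0
            for _ in range(100):
                attempt: list = []
                s_end = _evolve_branch(
                    s0, float(tree.ages[v]), float(tree.ages[c]),
                    params, space, schedule, idx, rng, attempt, int(c),
                )
                if s_end != 0:
                    branch_events.extend(attempt)
                    break
            if s_end == 0:
                return None
            node_states[c] = s_end
    tip_ranges = {
        lab: space.labels(int(node_states[i])) for i, lab in enumerate(tree.tip_labels)
    }
    return DECHistory(tip_ranges, node_states, branch_events, clado_events)


def _evolve_branch(state, age_hi, age_lo, params, space, schedule, idx, rng,
                   log, child_id):
    age = age_hi
    while age > age_lo + 1e-12:
        epoch = schedule.epoch_of(age)
        m = schedule.multipliers[epoch]
        # next epoch boundary below current age
        nxt = max([b for b in schedule.breaks if age_lo < b < age], default=age_lo)
        R = space.states[state]
        if not R:
            return 0
        moves, rates = [], []
        if len(R) < space.max_range_size:
            for a in range(space.k):
                if a in R:
                    continue
                r = params.d * sum(m[b, a] for b in R)
                if r > 0:
                    moves.append(("dispersal", a, idx[R | {a}]))
                    rates.append(r)
        for a in R:
            moves.append(("extirpation", a, idx[R - {a}]))
            rates.append(params.e)
        total = float(np.sum(rates))
        if total <= 0:
            age = nxt
            continue
        dt = rng.exponential(1.0 / total)
        if age - dt <= nxt:
            age = nxt
            continue
        age -= dt
        kind, area, new_state = moves[int(rng.choice(len(moves), p=np.array(rates) / total))]
        log.append({
            "branch_child": child_id, "age": float(age), "kind": kind,
            "area": space.scheme.labels[area],
            "from_state": int(state), "to_state": int(new_state),
        })
        state = new_state
        if state == 0:
            return 0
    return state


# ---------------------------------------------------------------------------
# climate grids


def _grid_axes(spacing):
    if abs((180.0 / spacing) - round(180.0 / spacing)) > 1e-9:
        raise ValueError("grid spacing must divide 180")
    lats = np.arange(-90 + spacing / 2, 90, spacing)
    lons = np.arange(-180 + spacing / 2, 180, spacing)
    return lats, lons


def _blobby_mask(rng, lats, lons, land_fraction):
    """Seeded blobby continents: thresholded sum of random Gaussian bumps."""
    Lat, Lon = np.meshgrid(lats, lons, indexing="ij")
    f = np.zeros_like(Lat)
    for _ in range(12):
        clat = rng.uniform(-70, 70)
        clon = rng.uniform(-180, 180)
        amp = rng.uniform(0.5, 1.5)
        slat = rng.uniform(15, 40)
        slon = rng.uniform(20, 60)
        dlon = np.abs((Lon - clon + 180) % 360 - 180)
        f += amp * np.exp(-((Lat - clat) ** 2) / (2 * slat**2)
                          - (dlon**2) / (2 * slon**2))
    cut = np.quantile(f, 1.0 - land_fraction)
    return f >= cut


def generate_climate_grid(
    config: SimulationConfig,
    slice_name: str,
    age_ma: float,
    rng: np.random.Generator | None = None,
    land_mask: str | np.ndarray = "blobby",
) -> dict[str, ClimateGrid]:
    """All four climate variables for one stage slice.

    MAT falls linearly with |latitude| from the equatorial value; MAP drops
    by the arid-trough depth inside the configured latitude band;
    temperature seasonality grows with |latitude|. ``land_mask`` may be
    "blobby" (seeded continents), "all" (no sea) or an explicit array.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lats, lons = _grid_axes(config.grid_spacing_deg)
    Lat = np.broadcast_to(lats[:, None], (len(lats), len(lons))).astype(float)
    shape = Lat.shape
    if isinstance(land_mask, str):
        if land_mask == "all":
            mask = np.ones(shape, dtype=bool)
        elif land_mask == "blobby":
            mask = _blobby_mask(rng, lats, lons, config.land_fraction)
        else:
            raise ValueError("land_mask must be 'blobby', 'all' or an array")
    else:
        mask = np.asarray(land_mask, dtype=bool)

    mat = (config.equator_mat_c - config.mat_gradient_c_per_deg * np.abs(Lat)
           + rng.normal(0, config.mat_noise_sd, shape) if config.mat_noise_sd > 0
           else config.equator_mat_c - config.mat_gradient_c_per_deg * np.abs(Lat))
    lo, hi = min(config.arid_band), max(config.arid_band)
    in_band = (Lat >= lo) & (Lat <= hi)
    mapv = config.map_base_mm - config.arid_trough_mm * in_band
    if config.map_noise_sd > 0:
        mapv = mapv + rng.normal(0, config.map_noise_sd, shape)
    mapv = np.clip(mapv, 0.0, None)
    tseas = config.tseas_base_c + config.tseas_gradient_c_per_deg * np.abs(Lat)
    if config.tseas_noise_sd > 0:
        tseas = tseas + rng.normal(0, config.tseas_noise_sd, shape)
    pseas = np.full(shape, config.pseas_base_mm)
    if config.pseas_noise_sd > 0:
        pseas = pseas + rng.normal(0, config.pseas_noise_sd, shape)
    pseas = np.clip(pseas, 0.0, None)
    fields = {"MAT": mat, "MAP": mapv, "TSEAS": tseas, "PSEAS": pseas}
    return {
        var: ClimateGrid(
            variable=var, slice_name=slice_name, age_ma=age_ma,
            lats=lats, lons=lons, values=np.asarray(vals, dtype=float),
            land=mask,
        )
        for var, vals in fields.items()
    }


def generate_climate_stack(
    config: SimulationConfig,
    stages: StageTable = DEFAULT_STAGES,
    land_mask: str | np.ndarray = "blobby",
) -> dict[str, dict[str, ClimateGrid]]:
    """slice name -> {variable -> grid} for every stage slice, one RNG
    stream per slice derived from the config seed."""
    out = {}
    for i, (name, age) in enumerate(stages.slices):
        rng = np.random.default_rng([config.seed, i])
        out[name] = generate_climate_grid(config, name, age, rng, land_mask)
    return out


# ---------------------------------------------------------------------------
# occurrence sampling


def area5_from_coords(lat: float, lon: float) -> str:
    if lat < -35:
        return "southern Gondwana"
    if lat < -10:
        return "northern Gondwana"
    if lat < 15:
        return "equatorial belt"
    return "eastern Laurasia" if lon >= 0 else "western Laurasia"


def area8_from_coords(lat: float, lon: float) -> str:
    if lon < -30:  # the Americas
        if lat >= 0:
            return "western North America" if lon < -60 else "eastern North America"
        return "Brazil" if lat > -40 else "Argentina"
    if lat >= 0:
        return "Europe + Russia"
    return "South Africa" if lat > -48 else "Indian subcontinent + Madagascar"


def sample_occurrences(
    stack: dict,
    config: SimulationConfig,
    n_per_clade: dict[str, int],
    stages: StageTable = DEFAULT_STAGES,
    rng: np.random.Generator | None = None,
) -> list[OccurrenceRecord]:
    """Draw occurrences from Gaussian climatic niches in (MAT, MAP).

    Land cells of a uniformly chosen stage slice are weighted by the
    clade's niche density at their (MAT, MAP); sampled cells become records
    with that slice as their stage and area codes from the coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = []
    slice_names = [s for s in stack]
    for clade, n in n_per_clade.items():
        if n < 1:
            raise ValueError(f"n for clade {clade!r} must be >= 1")
        mat_mu, mat_sd, map_mu, map_sd = config.niche_truth[clade]
        for i in range(n):
            sl = slice_names[int(rng.integers(len(slice_names)))]
            grids = stack[sl]
            land = grids["MAT"].land
            ii, jj = np.nonzero(land)
            mat = grids["MAT"].values[ii, jj]
            mapv = grids["MAP"].values[ii, jj]
            w = (np.exp(-0.5 * ((mat - mat_mu) / mat_sd) ** 2)
                 * np.exp(-0.5 * ((mapv - map_mu) / map_sd) ** 2))
            tot = w.sum()
            if tot <= 0:
                raise ValueError(f"niche for {clade!r} has zero weight on the grid")
            pick = int(rng.choice(len(w), p=w / tot))
            lat = float(grids["MAT"].lats[ii[pick]])
            lon = float(grids["MAT"].lons[jj[pick]])
            records.append(OccurrenceRecord(
                specimen_id=f"{clade[:3].upper()}-{i:04d}",
                taxon=f"{clade}_taxon_{i}",
                clade=clade,
                locality_id=f"loc_{clade[:3]}_{i:04d}",
                palaeolat=lat,
                palaeolon=lon,
                stage_early=sl,
                stage_late=sl,
                area5=area5_from_coords(lat, lon),
                area8=area8_from_coords(lat, lon),
            ).validate(stages))
    return records


# ---------------------------------------------------------------------------
# survey-mimic fixture (deterministic, no RNG)


def _rec(i, taxon, clade, lat, lon, early, late, locality=None):
    return OccurrenceRecord(
        specimen_id=f"PM-{i:03d}",
        taxon=taxon,
        clade=clade,
        locality_id=locality or f"L{i:03d}",
        palaeolat=lat,
        palaeolon=lon,
        stage_early=early,
        stage_late=late,
        area5=area5_from_coords(lat, lon),
        area8=area8_from_coords(lat, lon),
    )


def triassic_survey_occurrences() -> list[OccurrenceRecord]:
    """Raw specimen table mirroring a published survey's filter behaviour.

    65 rows; the 111-km collapsing keeps 54 (24 pterosaur / 30 lagerpetid).
    Among records usable for climate extraction, 8 span two stage slices;
    the niche groups come out 23 pterosaur / 9 pre-Norian lagerpetid /
    17 Norian-Rhaetian lagerpetid: one pterosaur range runs into the
    Hettangian (no climate slice) and four lagerpetids straddle the
    Carnian/Norian boundary (no single group).
    """
    rows: list[OccurrenceRecord] = []
    i = iter(range(1, 200))

    def add(*args, **kw):
        rows.append(_rec(next(i), *args, **kw))

    # --- pterosaurs: middle Norian x8 (two Italian taxa 50 km apart stay
    # distinct; a same-taxon duplicate 40 km away collapses)
    add("Eotethysdraco_a", "pterosaur", 27.1, 12.0, "middle Norian", "middle Norian")
    add("Eotethysdraco_b", "pterosaur", 27.4, 12.3, "middle Norian", "middle Norian")
    add("Eotethysdraco_a", "pterosaur", 27.3, 12.2, "middle Norian", "middle Norian")  # dup
    add("Chinledraco_a", "pterosaur", 8.5, -62.0, "middle Norian", "middle Norian",
        locality="PFV456")
    add("Chinledraco_a", "pterosaur", 8.7, -62.2, "middle Norian", "middle Norian",
        locality="PFV456b")  # dup
    add("Dockumdraco_a", "pterosaur", 7.0, -55.0, "middle Norian", "middle Norian")
    add("Tethysdraco_c", "pterosaur", 24.0, 18.0, "middle Norian", "middle Norian")
    add("Tethysdraco_d", "pterosaur", 22.5, 25.0, "middle Norian", "middle Norian")
    add("Tethysdraco_e", "pterosaur", 30.0, 8.0, "middle Norian", "middle Norian")
    add("Alpinodraco_f", "pterosaur", 29.0, 15.5, "middle Norian", "middle Norian")
    # --- late Norian x6 (one duplicate pair)
    add("Soltodraco_a", "pterosaur", 26.0, 13.5, "late Norian", "late Norian")
    add("Soltodraco_a", "pterosaur", 26.3, 13.2, "late Norian", "late Norian")  # dup
    add("Owlrockdraco", "pterosaur", 9.5, -60.5, "late Norian", "late Norian")
    add("Groenlanddraco", "pterosaur", 41.0, -15.0, "late Norian", "late Norian")
    add("Andeandraco", "pterosaur", -38.5, -50.0, "late Norian", "late Norian")
    add("Tethysdraco_g", "pterosaur", 25.5, 21.0, "late Norian", "late Norian")
    add("Tethysdraco_h", "pterosaur", 28.5, 10.5, "late Norian", "late Norian")
    # --- Rhaetian x4
    add("Rhaetodraco_a", "pterosaur", 27.0, 14.5, "Rhaetian", "Rhaetian")
    add("Rhaetodraco_b", "pterosaur", 31.0, 6.0, "Rhaetian", "Rhaetian")
    add("Rhaetodraco_c", "pterosaur", 43.0, -12.0, "Rhaetian", "Rhaetian")
    add("Rhaetodraco_d", "pterosaur", 24.5, 28.0, "Rhaetian", "Rhaetian")
    # --- early Norian x3 (incl. a PEFO-style Chinle specimen + duplicate)
    add("Chinle_early", "pterosaur", 8.0, -61.0, "early Norian", "early Norian",
        locality="PEFO 45782 site")
    add("Chinle_early", "pterosaur", 8.2, -61.3, "early Norian", "early Norian")  # dup
    add("Kalgarydraco", "pterosaur", 6.5, -54.0, "early Norian", "early Norian")
    add("Newarkdraco", "pterosaur", 15.0, -65.0, "early Norian", "early Norian")
    # --- two-stage pterosaurs x2 (early-middle Norian)
    add("Spandraco_a", "pterosaur", 7.5, -56.5, "early Norian", "middle Norian")
    add("Spandraco_b", "pterosaur", 23.0, 16.0, "early Norian", "middle Norian")
    # --- range running into the Jurassic (no climate slice -> dropped there)
    add("Nuggetdraco", "pterosaur", 12.0, -58.0, "late Norian", "Hettangian")

    # --- lagerpetids: pre-Norian x9
    add("Kongonaphon_like", "lagerpetid", -53.7, 35.0, "Ladinian", "Ladinian")
    add("Mandasuchus_assoc", "lagerpetid", -52.0, 30.0, "Ladinian", "Ladinian")
    add("Lagerpeton_a", "lagerpetid", -40.6, -48.0, "Ladinian", "Ladinian")
    add("Lagerpeton_b", "lagerpetid", -41.0, -46.0, "early Carnian", "early Carnian")
    add("Ixalerpeton_a", "lagerpetid", -39.7, -42.0, "early Carnian", "early Carnian")
    add("Ixalerpeton_a", "lagerpetid", -39.9, -42.3, "early Carnian", "early Carnian")  # dup
    add("PVSJ883_like", "lagerpetid", -40.2, -47.0, "early Carnian", "early Carnian")
    add("Buriolestes_assoc", "lagerpetid", -38.9, -41.0, "late Carnian", "late Carnian")
    add("Ischigualasto_lag", "lagerpetid", -41.5, -49.0, "late Carnian", "late Carnian")
    add("FreeState_lag", "lagerpetid", -42.8, 20.0, "late Carnian", "late Carnian")
    # --- Carnian/Norian straddlers x4 (two-stage, ungrouped)
    add("Straddle_a", "lagerpetid", -39.0, -44.0, "late Carnian", "early Norian")
    add("Straddle_b", "lagerpetid", 7.8, -57.5, "late Carnian", "early Norian")
    add("Straddle_c", "lagerpetid", -37.5, -45.5, "late Carnian", "early Norian")
    add("Straddle_d", "lagerpetid", 9.0, -59.0, "late Carnian", "early Norian")
    # --- Norian-Rhaetian x17
    add("Dromomeron_a", "lagerpetid", 8.3, -60.0, "early Norian", "early Norian",
        locality="Hayden Quarry")
    add("Dromomeron_a", "lagerpetid", 8.5, -60.3, "early Norian", "early Norian")  # dup
    add("Dromomeron_b", "lagerpetid", 6.8, -55.5, "early Norian", "early Norian")
    add("Eagle_basin_lag", "lagerpetid", 10.5, -63.0, "early Norian", "early Norian")
    add("Dromomeron_c", "lagerpetid", 8.9, -61.8, "middle Norian", "middle Norian")
    add("Dromomeron_c", "lagerpetid", 9.1, -62.0, "middle Norian", "middle Norian")  # dup
    add("Dromomeron_d", "lagerpetid", 7.2, -56.0, "middle Norian", "middle Norian")
    add("Dromomeron_e", "lagerpetid", 10.0, -64.5, "middle Norian", "middle Norian")
    add("Tecovas_lag", "lagerpetid", 6.2, -53.5, "middle Norian", "middle Norian")
    add("SantaRosa_lag", "lagerpetid", 11.0, -66.0, "middle Norian", "middle Norian")
    add("Dromomeron_f", "lagerpetid", 9.8, -63.8, "late Norian", "late Norian")
    add("Dromomeron_f", "lagerpetid", 9.6, -64.0, "late Norian", "late Norian")  # dup
    add("Dromomeron_gigas_like", "lagerpetid", -38.0, -51.0, "late Norian", "late Norian")
    add("Faxinalipterus_like", "lagerpetid", -39.4, -43.5, "late Norian", "late Norian")
    add("Apachean_lag", "lagerpetid", 8.6, -59.5, "late Norian", "late Norian")
    add("Rhaetian_lag_a", "lagerpetid", 16.2, -68.0, "Rhaetian", "Rhaetian")
    add("Rhaetian_lag_b", "lagerpetid", 14.8, -66.5, "Rhaetian", "Rhaetian")
    add("Rhaetian_lag_c", "lagerpetid", 27.5, 11.0, "Rhaetian", "Rhaetian")
    # --- two-stage lagerpetids x2 (middle-late Norian)
    add("Spanlag_a", "lagerpetid", 8.1, -58.5, "middle Norian", "late Norian")
    add("Spanlag_b", "lagerpetid", 9.3, -65.5, "middle Norian", "late Norian")

    # three more duplicates to reach the raw count (collapse away)
    add("Tethysdraco_c", "pterosaur", 24.2, 18.2, "middle Norian", "middle Norian")
    add("Rhaetian_lag_a", "lagerpetid", 16.0, -67.8, "Rhaetian", "Rhaetian")
    add("Dromomeron_b", "lagerpetid", 6.6, -55.3, "early Norian", "early Norian")

    return [r.validate() for r in rows]


def triassic_survey_grids(config: SimulationConfig | None = None
                      ) -> dict[str, dict[str, ClimateGrid]]:
    """All-land climate stack for the survey-mimic fixture (every occurrence
    extracts cleanly; the sea-fallback path is exercised elsewhere)."""
    if config is None:
        config = SimulationConfig(seed=1234)
    return generate_climate_stack(config, land_mask="all")
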