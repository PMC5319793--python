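"""Synthetic data with the statistical structure the pipeline assumes.

The generator replaces the fly RNA-seq / mmPCR-seq compendium with
fully specified truth: editing sites are born on branches of a species
tree and their levels evolve as a reflected Gaussian random walk; reads
are binomial draws over negative-binomial coverage with a 1% A-to-G
error floor and an ADAR-null sample; sequences carry planted hairpin
duplexes and motif triplets, optionally coupled to editing levels
through a logistic link; conservation tracks carry planted constrained
windows; and expression tables carry shifts for 3'UTR-edited genes plus
UTRs whose editing creates a miRNA seed match.

Every stochastic draw flows from one seeded generator; module-level
substreams are derived by hashing the substream name with the seed, so
identical (seed, config) pairs give byte-identical outputs.

These are generative stand-ins chosen to be realistic for fly editing
data, not estimates from any particular dataset; see the methods note
for what they do and do not emulate.
"""

from __future__ import annotations

import io as _io
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConservationTrack, revcomp

__all__ = [
    "DEFAULT_TREE",
    "SimConfig",
    "SimTruth",
    "substream",
    "simulate_levels",
    "simulate_reads",
    "simulate_sequences",
    "simulate_conservation",
    "simulate_expression",
    "simulate_feature_rows",
]

#: Ultrametric six-species tree with mel-like divergence times (Myr):
#: mel-sim 5, mel-yak 10, mel-ana 30, mel-pse 45, mel-vir 60.
DEFAULT_TREE = "(((((mel:5,sim:5):5,yak:10):20,ana:30):15,pse:45):15,vir:60);"

_ALPHABET = np.array(list("ACGU"))
_CATEGORIES = ("nonsynonymous", "synonymous", "3UTR", "5UTR", "intron")
_CATEGORY_P = (0.40, 0.15, 0.25, 0.05, 0.15)

WINDOW_HALF = 200          # planted windows are 401 nt with the site at 200
SITE_OFFSET = 200


@dataclass
class SimConfig:
    tree: str = DEFAULT_TREE
    anchor: str = "mel"
    n_sites: int = 1000
    n_genes: int = 200
    coverage_mean: float = 100.0
    coverage_dispersion: float = 5.0
    error_rate: float = 0.01
    level_walk_sd: float = 0.01          # per sqrt(Myr)
    initial_level_range: tuple = (0.2, 0.8)
    p_stem: float = 0.7                  # probability a site gets a planted stem
    stem_np_range: tuple = (21, 33)      # paired bases of planted stems
    motif_effect: float = 0.0
    structure_effect: float = 0.0
    p_disrupt: float = 0.3               # cis-coupled: per-species loss of a property
    p_motif_disrupt: float = 0.3         # which property is lost: motif vs stem
    p_motif_drift: float = 0.01          # quiet motif change in non-disrupted species
    stem_drift: float = 3.0              # Poisson mean of pairs lost in other species
    background_mutation_rate: float = 0.005
    fraction_high: float = 0.2
    fraction_moderate: float = 0.2
    expression_shift: float = 0.5
    expression_sigma: float = 0.3
    n_seed_gain: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        for name in ("coverage_mean", "coverage_dispersion", "level_walk_sd",
                     "expression_shift", "expression_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the observables."""

    sites: pd.DataFrame          # per-site annotations and planted properties
    levels: pd.DataFrame         # sites x species true editing levels
    species: list[str]
    anchor: str
    tree: str
    genes: pd.DataFrame | None = None
    seed_gains: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named substream of the global seed (stable across runs)."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# tree helpers

def _parse_tree(newick: str):
    from skbio import TreeNode

    tree = TreeNode.read(_io.StringIO(newick))
    leaves = [t.name for t in tree.tips()]
    return tree, leaves


def _branches(tree, mean_weight: float | None = None):
    """(node, weight, descendant leaves) for every branch incl. a root
    pseudo-branch so pan-edited (oldest) sites exist."""
    out = []
    lengths = []
    for node in tree.preorder(include_self=False):
        length = node.length or 0.0
        lengths.append(length)
        out.append((node, length, frozenset(t.name for t in node.tips())
                    if not node.is_tip() else frozenset([node.name])))
    root_weight = mean_weight if mean_weight is not None else float(np.mean(lengths))
    out.insert(0, (tree, root_weight, frozenset(t.name for t in tree.tips())))
    return out


def _reflect(x: float) -> float:
    """Reflect a walk value back into [0, 1]."""
    while x < 0 or x > 1:
        if x < 0:
            x = -x
        if x > 1:
            x = 2 - x
    return x


def _divergence_times(tree, anchor: str) -> dict[str, float]:
    """Path distance / 2 from the anchor to every leaf (Myr)."""
    anchor_tip = next(t for t in tree.tips() if t.name == anchor)
    out = {}
    for tip in tree.tips():
        out[tip.name] = 0.0 if tip.name == anchor else \
            float(anchor_tip.distance(tip)) / 2.0
    return out


# ---------------------------------------------------------------------------
# levels along the phylogeny

def simulate_levels(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Site birth on branches + reflected Gaussian random walk of levels.

    Each site is born on a branch chosen with probability proportional
    to branch length (a root pseudo-branch, weighted by the mean branch
    length, allows sites older than the root split).  The level starts
    uniform in ``initial_level_range`` at the birth node and evolves
    down every descendant branch with sd = level_walk_sd * sqrt(branch
    length), reflected into [0, 1].  Species outside the birth clade
    have level exactly 0.
    """
    rng = substream(config.rng_seed, "levels")
    tree, species = _parse_tree(config.tree)
    if len(species) == 0:
        raise ValueError("tree has no leaves")
    branches = _branches(tree)
    weights = np.array([b[1] for b in branches], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    weights = weights / weights.sum()
    times = _divergence_times(tree, config.anchor)

    site_ids = [f"s{i:05d}" for i in range(config.n_sites)]
    lo, hi = config.initial_level_range
    levels = np.zeros((config.n_sites, len(species)))
    birth_names = []
    age_classes = []
    col = {sp: k for k, sp in enumerate(species)}

    for i in range(config.n_sites):
        b = rng.choice(len(branches), p=weights)
        node, _, clade = branches[b]
        birth_names.append("root" if node.is_root() else (node.name or f"node{b}"))
        start = float(rng.uniform(lo, hi))

        def walk(n, level):
            if n.is_tip():
                levels[i, col[n.name]] = level
                return
            for child in n.children:
                step = rng.normal(0.0, config.level_walk_sd * np.sqrt(child.length or 0.0))
                walk(child, _reflect(level + step))

        walk(node, start)
        edited = [sp for sp in clade if levels[i, col[sp]] > 0]
        if config.anchor in clade:
            age = max(edited, key=lambda sp: times[sp]) if edited else config.anchor
        else:
            age = None
        age_classes.append(age)

    level_df = pd.DataFrame(levels, index=site_ids, columns=species)
    rng_cat = substream(config.rng_seed, "categories")
    categories = rng_cat.choice(_CATEGORIES, size=config.n_sites, p=_CATEGORY_P)
    genes = [f"g{i % config.n_genes:04d}" for i in range(config.n_sites)]
    sites = pd.DataFrame({
        "site_id": site_ids,
        "gene": genes,
        "category": categories,
        "birth_branch": birth_names,
        "age_class": age_classes,
        "contig": site_ids,
        "pos": SITE_OFFSET,
        "strand": "+",
    })
    truth = SimTruth(sites=sites, levels=level_df, species=species,
                     anchor=config.anchor, tree=config.tree)
    truth.extras["divergence_times"] = times
    return level_df, truth


# ---------------------------------------------------------------------------
# reads

def simulate_reads(true_levels: pd.DataFrame, config: SimConfig,
                   samples=("male", "female"),
                   null_sample: bool = True) -> pd.DataFrame:
    """Binomial read sampling over negative-binomial coverage.

    Per (site, species, sample): coverage ~ NB(coverage_mean,
    dispersion); G reads ~ Binomial(coverage, level + error*(1-level));
    non-G reads are A except C/T errors at error_rate/2 each.  An
    ADAR-null sample (anchor species, level forced to 0) is appended
    when ``null_sample``.
    """
    rng = substream(config.rng_seed, "reads")
    err = config.error_rate
    k = config.coverage_dispersion
    p_nb = k / (k + config.coverage_mean)
    frames = []

    def draw(sample_id, levels: np.ndarray):
        n = levels.size
        cov = rng.negative_binomial(k, p_nb, size=n)
        p_g = levels + err * (1.0 - levels)
        n_g = rng.binomial(cov, p_g)
        rest = cov - n_g
        # C then T errors among the non-G reads, A takes the remainder
        n_c = rng.binomial(rest, err / 2)
        n_t = rng.binomial(rest - n_c, (err / 2) / (1 - err / 2))
        n_a = rest - n_c - n_t
        return pd.DataFrame({
            "site_id": true_levels.index, "sample_id": sample_id, "ref_base": "A",
            "n_A": n_a, "n_C": n_c, "n_G": n_g, "n_T": n_t,
        })

    for species in true_levels.columns:
        for sample in samples:
            frames.append(draw(f"{species}_{sample}",
                               true_levels[species].to_numpy(dtype=float)))
    if null_sample:
        anchor = config.anchor if config.anchor in true_levels.columns \
            else true_levels.columns[0]
        frames.append(draw(f"{anchor}_adar_null", np.zeros(len(true_levels))))
    df = pd.concat(frames, ignore_index=True)
    df["coverage"] = df[["n_A", "n_C", "n_G", "n_T"]].sum(axis=1)
    return df


# ---------------------------------------------------------------------------
# sequences

_HIGH_TRIPLETS = ("UAG", "UAA", "AAG", "CAG")
_WORST_TRIPLET = "GAC"  # disfavoured context: G at -1, C at +1


def _triplet_quality(t: str) -> int:
    return int(t[0] == "U") + int(t[2] == "G")


def _draw_triplet(rng, motif_effect: float) -> str:
    triplets = [x + "A" + y for x in "ACGU" for y in "ACGU"]
    w = np.array([np.exp(motif_effect * _triplet_quality(t)) for t in triplets])
    return triplets[rng.choice(len(triplets), p=w / w.sum())]


_PAIRABLE = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def _break_stem_extensions(seq, e_lo, e_hi, s_lo, s_hi, centre,
                           max_gap: int = 12, min_run: int = 3,
                           rounds: int = 60) -> bool:
    """Destroy accidental complementary runs that would extend a
    planted stem past its ends, so the planted duplex is exactly the
    maximal one.  Mutated bases are set equal to their would-be
    partner (identical bases never pair) and frozen so later edits
    cannot reopen them.  Returns True when the window converged."""
    planted = set(range(e_lo, e_hi)) | set(range(s_lo, s_hi)) | \
        {centre - 1, centre, centre + 1}
    frozen: set[int] = set()
    L = len(seq)

    def untouchable(pos):
        return pos in planted or pos in frozen

    def run_at(p0, q0, dp, dq):
        t = 0
        while True:
            p, q = p0 + dp * t, q0 + dq * t
            if not (0 <= p < L and 0 <= q < L) or abs(p - q) <= 4:
                break
            if p in planted or q in planted:
                break
            if (str(seq[p]), str(seq[q])) not in _PAIRABLE:
                break
            t += 1
        return t

    corners = [
        (e_lo - 1, s_hi, -1, +1),   # outward extension
        (e_hi, s_lo - 1, +1, -1),   # inward extension (into the loop)
    ]
    for _ in range(rounds):
        dirty = False
        stuck = False
        for p0, q0, dp, dq in corners:
            for a in range(max_gap):
                for b in range(max_gap):
                    # a gap-free diagonal continuation extends the stem at
                    # zero alignment cost, so any run is broken there;
                    # offset continuations pay a bulge and need >= min_run
                    threshold = 1 if (a == 0 and b == 0) else min_run
                    p_start, q_start = p0 + dp * a, q0 + dq * b
                    t = run_at(p_start, q_start, dp, dq)
                    if t < threshold:
                        continue
                    broken = False
                    for k in range(t):
                        p, q = p_start + dp * k, q_start + dq * k
                        target, partner = (q, p) if not untouchable(q) else (p, q)
                        if untouchable(target):
                            continue
                        seq[target] = seq[partner]
                        frozen.add(target)
                        broken = True
                        break
                    if broken:
                        dirty = True
                    else:
                        stuck = True
        if not dirty:
            return not stuck
    return False


def simulate_sequences(truth: SimTruth, config: SimConfig):
    """Per-species windows with planted motif triplets and hairpins.

    Each site sits at offset 200 of a 401-nt window (one contig per
    site).  With probability ``p_stem`` a perfect hairpin is planted
    whose editing arm covers the site; the motif triplet is written at
    positions -1/+1.  In species where the site is absent
    (anchor >= 10%, species <= 1.5%) at least one planted property is
    destroyed: the motif with probability ``p_motif_disrupt``,
    otherwise the stem (ECS arm shuffled).  When ``structure_effect``
    or ``motif_effect`` is positive the anchor's true level is
    overridden by a logistic function of the planted paired-base count
    and motif quality, so the cis-coupling downstream models look for
    is real; with both effects at 0 the planted structures are
    independent of levels.

    Returns (seqs, site_table, stems) where ``seqs`` maps species ->
    {contig: sequence}; truth.sites gains the planted columns.
    """
    rng = substream(config.rng_seed, "sequences")
    sites = truth.sites
    n = len(sites)
    L = 2 * WINDOW_HALF + 1
    c = SITE_OFFSET
    coupled = config.structure_effect > 0 or config.motif_effect > 0

    triplets, np_list, stem_coords = [], [], []
    anchor_windows = []
    for i in range(n):
        want_stem = rng.uniform() < config.p_stem
        n_p = int(rng.integers(*config.stem_np_range)) if want_stem else 0
        trip = _draw_triplet(rng, config.motif_effect)
        for attempt in range(10):
            seq = rng.choice(_ALPHABET, size=L)
            seq[c - 1], seq[c], seq[c + 1] = trip[0], "A", trip[2]
            if not want_stem:
                coords = None
                break
            d = int(rng.integers(4, n_p - 4))
            e_lo = c - d
            e_hi = e_lo + n_p
            loop = 10
            s_lo = e_hi + loop
            s_hi = s_lo + n_p
            arm = "".join(seq[e_lo:e_hi])
            seq[s_lo:s_hi] = list(revcomp(arm))
            coords = (e_lo, e_hi, s_lo, s_hi)
            if _break_stem_extensions(seq, e_lo, e_hi, s_lo, s_hi, c):
                break
        else:
            raise RuntimeError("could not plant a clean stem after bounded retries")
        triplets.append(trip)
        np_list.append(n_p)
        stem_coords.append(coords)
        anchor_windows.append(seq)

    np_arr = np.array(np_list)
    qual = np.array([_triplet_quality(t) for t in triplets], dtype=float)
    # species descending from the birth branch; in the cis-coupled
    # regime every species carries the locus and absence arises only
    # from cis disruption (the regime models an orthologous site set)
    if coupled:
        clade = truth.levels.notna()
    else:
        clade = truth.levels > 0

    # per-species cis state: which planted properties survive where
    disrupted_motif = {sp: np.zeros(n, dtype=bool) for sp in truth.species}
    disrupted_stem = {sp: np.zeros(n, dtype=bool) for sp in truth.species}
    stem_loss = {sp: np.zeros(n, dtype=int) for sp in truth.species}
    species_triplet = {sp: list(triplets) for sp in truth.species}

    if coupled:
        for sp in truth.species:
            if sp == truth.anchor:
                continue
            for i in range(n):
                if not clade[sp].iloc[i]:
                    continue
                if rng.uniform() < config.p_disrupt:
                    # absence loses the stem, and often the motif with it
                    if np_list[i]:
                        disrupted_stem[sp][i] = True
                    if np_list[i] == 0 or rng.uniform() < config.p_motif_disrupt:
                        disrupted_motif[sp][i] = True
                        species_triplet[sp][i] = _WORST_TRIPLET
                else:
                    if np_list[i]:
                        stem_loss[sp][i] = min(int(rng.poisson(config.stem_drift)),
                                               max(np_list[i] - 10, 0))
                    if rng.uniform() < config.p_motif_drift:
                        species_triplet[sp][i] = _draw_triplet(rng, 0.0)

        # logistic link: each species' level reflects its own feature state
        def _level(n_p_eff, q_eff):
            z = (-1.0 + config.structure_effect * (n_p_eff - 26.0) / 6.0
                 + config.motif_effect * (q_eff - 1.0))
            return 1.0 / (1.0 + np.exp(-(z + rng.normal(0.0, 0.25))))

        for sp in truth.species:
            values = np.zeros(n)
            for i in range(n):
                if not clade[sp].iloc[i]:
                    continue
                if sp == truth.anchor:
                    values[i] = _level(np_arr[i], qual[i])
                else:
                    n_eff = 0 if disrupted_stem[sp][i] else np_arr[i] - stem_loss[sp][i]
                    q_eff = _triplet_quality(species_triplet[sp][i])
                    values[i] = _level(n_eff, q_eff)
            truth.levels[sp] = values

    anchor_levels = truth.levels[truth.anchor]
    seqs: dict[str, dict[str, str]] = {}
    for sp in truth.species:
        contigs = {}
        for i, site_id in enumerate(sites["site_id"]):
            seq = anchor_windows[i].copy()
            protected = {c - 1, c, c + 1}
            if stem_coords[i]:
                e_lo, e_hi, s_lo, s_hi = stem_coords[i]
                protected |= set(range(e_lo, e_hi)) | set(range(s_lo, s_hi))
            # neutral background divergence away from planted features
            if sp != truth.anchor and config.background_mutation_rate > 0:
                hits = np.flatnonzero(rng.uniform(size=L) < config.background_mutation_rate)
                for h in hits:
                    if int(h) not in protected:
                        seq[h] = rng.choice(_ALPHABET)
            if not coupled and sp != truth.anchor:
                # uncoupled regime: Presence/Absence sites still lose a
                # planted property so the sequence record matches the calls
                is_absent = (anchor_levels.iloc[i] >= 0.10
                             and truth.levels[sp].iloc[i] <= 0.015)
                if is_absent:
                    if stem_coords[i] is None or rng.uniform() < config.p_motif_disrupt:
                        disrupted_motif[sp][i] = True
                        species_triplet[sp][i] = _WORST_TRIPLET
                    else:
                        disrupted_stem[sp][i] = True
            trip_sp = species_triplet[sp][i]
            seq[c - 1], seq[c + 1] = trip_sp[0], trip_sp[2]
            if stem_coords[i] is not None:
                e_lo, e_hi, s_lo, s_hi = stem_coords[i]
                if disrupted_stem[sp][i]:
                    arm = seq[s_lo:s_hi].copy()
                    seq[s_lo:s_hi] = arm[rng.permutation(len(arm))]
                else:
                    # quiet drift: the outermost pairs are unpaired by
                    # setting the ECS base equal to its partner
                    for k in range(stem_loss[sp][i]):
                        seq[s_hi - 1 - k] = seq[e_lo + k]
            contigs[site_id] = "".join(seq)
        seqs[sp] = contigs

    sites = sites.copy()
    sites["motif_triplet"] = triplets
    sites["stem_np"] = np_list
    sites["stem_coords"] = stem_coords
    truth.sites = sites
    truth.extras["disrupted_motif"] = disrupted_motif
    truth.extras["disrupted_stem"] = disrupted_stem
    truth.extras["stem_loss"] = stem_loss
    truth.extras["species_triplet"] = species_triplet

    site_table = pd.DataFrame({
        "contig": sites["site_id"],
        "start": SITE_OFFSET,
        "end": SITE_OFFSET + 1,
        "site_id": sites["site_id"],
        "category": sites["category"],
        "strand": "+",
        "gene": sites["gene"],
    })
    return seqs, site_table


# ---------------------------------------------------------------------------
# conservation

def simulate_conservation(truth: SimTruth, config: SimConfig) -> ConservationTrack:
    """Planted constraint classes over each site's window.

    Background scores ~ Beta(2, 2) (mean 0.5); "high" sites get both
    S_region and F_region ~ Beta(57, 3) (mean 0.95); "moderate" sites
    elevate the S_region only; "none" sites are background throughout.
    Class labels are written into truth.sites["constraint_class"].
    """
    rng = substream(config.rng_seed, "conservation")
    n = len(truth.sites)
    classes = rng.choice(
        ["high", "moderate", "none"], size=n,
        p=[config.fraction_high, config.fraction_moderate,
           1 - config.fraction_high - config.fraction_moderate],
    )
    track = ConservationTrack()
    c = SITE_OFFSET
    L = 2 * WINDOW_HALF + 1
    s_lo, s_hi = c - 15, c + 31
    f_lo, f_hi = s_lo - 46, s_hi + 46
    for i, site_id in enumerate(truth.sites["site_id"]):
        values = rng.beta(2.0, 2.0, size=L)
        if classes[i] == "high":
            values[f_lo:f_hi] = rng.beta(57.0, 3.0, size=f_hi - f_lo)
        elif classes[i] == "moderate":
            values[s_lo:s_hi] = rng.beta(57.0, 3.0, size=s_hi - s_lo)
        track.add_segment(site_id, 0, values)
    truth.sites = truth.sites.copy()
    truth.sites["constraint_class"] = classes
    return track


# ---------------------------------------------------------------------------
# expression + miRNA

_SEED_CORES = ("AAGGCAC", "UCCCUGA", "GAGGUAC", "ACCGGUU", "UGGCAAC")


def _make_mirnas(rng) -> tuple[dict[str, str], pd.DataFrame]:
    mirnas = {}
    fractions = [0.30, 0.20, 0.10, 0.05, 0.0005]  # the last is below threshold
    rows = []
    for k, core in enumerate(_SEED_CORES):
        tail = "".join(rng.choice(_ALPHABET, size=14))
        mid = f"miR-{k + 1:03d}"
        mirnas[mid] = "U" + core + tail  # position 1 + seed 2-8 + tail
        rows.append((mid, fractions[k]))
    return mirnas, pd.DataFrame(rows, columns=["mirna_id", "fraction"])


def simulate_expression(truth: SimTruth, config: SimConfig):
    """Expression shifts for 3'UTR-edited genes, plus miRNA seed plants.

    Control genes draw log2FC ~ Normal(0, sigma); genes with one edited
    3'UTR site add ``expression_shift``, genes with several add twice
    that (expression rises when editing is lost, so the planted shift
    is positive in the mutant-vs-wild-type direction).  A configurable
    number of edited 3'UTRs contain an A whose editing creates an 8mer
    seed match to a bundled miRNA.

    Returns (expression table, utr sequences, mirnas, mirna expression
    table); truth.genes and truth.seed_gains record the ground truth.
    """
    rng = substream(config.rng_seed, "expression")
    anchor_levels = truth.levels[truth.anchor]
    sites = truth.sites
    edited = sites[anchor_levels.to_numpy() >= 0.05]
    utr_counts = edited[edited["category"] == "3UTR"].groupby("gene").size()
    other_edited = set(edited.loc[edited["category"] != "3UTR", "gene"])

    genes = sorted(set(sites["gene"]))
    rows = []
    for g in genes:
        n_utr = int(utr_counts.get(g, 0))
        shift = 0.0
        if n_utr == 1:
            shift = config.expression_shift
        elif n_utr > 1:
            shift = 2 * config.expression_shift
        log2fc = float(rng.normal(shift, config.expression_sigma))
        rows.append((g, log2fc, float(rng.lognormal(5, 1)), n_utr,
                     g in other_edited))
    expression = pd.DataFrame(rows, columns=["gene", "log2fc", "mean_expr",
                                             "n_utr3_sites", "other_edited"])

    mirnas, mirna_expr = _make_mirnas(rng)
    utr_genes = [g for g in genes if utr_counts.get(g, 0) > 0]
    utrs: dict[str, str] = {}
    gains = []
    gain_genes = utr_genes[: config.n_seed_gain]
    for g in utr_genes:
        utr = rng.choice(_ALPHABET, size=80)
        pos = 40
        if g in gain_genes:
            mid = "miR-001"
            target = revcomp(mirnas[mid][1:8]) + "A"  # 8mer site
            g_offsets = [k for k, b in enumerate(target[:7]) if b == "G"]
            off = int(rng.choice(g_offsets))
            planted = list(target)
            planted[off] = "A"  # editing restores the G
            utr[30:30 + len(planted)] = planted
            pos = 30 + off
            gains.append((g, mid, pos, "8mer", 30, 38))
        else:
            utr[pos] = "A"
        utrs[g] = "".join(utr)
    truth.genes = expression
    truth.seed_gains = pd.DataFrame(
        gains, columns=["gene", "mirna_id", "edit_pos", "match_type",
                        "match_start", "match_end"])
    truth.extras["utr_edit_positions"] = {
        g: [int(r[2]) for r in gains if r[0] == g] or [40] for g in utr_genes
    }
    return expression, utrs, mirnas, mirna_expr


# ---------------------------------------------------------------------------
# feature-level rows for the random-forest models

def simulate_feature_rows(n: int, seed: int = 0, level_effect: float = 0.0,
                          presence_effect: float = 0.0,
                          noise: float = 0.05,
                          effect_feature: str = "delta_free_energy") -> pd.DataFrame:
    """Model-matrix rows with an optional planted cis effect.

    Predictors are the anchor level plus standard-normal deltas of the
    motif score and the 8 structural features.  With ``level_effect``
    the other species' level is the anchor level plus
    level_effect * (planted feature delta) + noise; with
    ``presence_effect`` the other species' presence is thresholded on
    the planted feature delta.  With both effects 0 the outcome ignores
    every delta (pure-noise features).
    """
    from .rf import PREDICTOR_COLUMNS

    rng = substream(seed, "feature_rows")
    data = {"site_id": [f"r{i:05d}" for i in range(n)],
            "anchor_level": rng.uniform(0.1, 0.9, size=n)}
    for name in PREDICTOR_COLUMNS[1:]:
        data[name] = rng.normal(0.0, 1.0, size=n)
    df = pd.DataFrame(data)
    eff = df[effect_feature].to_numpy()
    if presence_effect > 0:
        score = -presence_effect * eff + rng.normal(0, noise * 10, size=n)
        df["other_level"] = np.where(score > 0, 0.30, 0.005)
    elif level_effect != 0:
        raw = df["anchor_level"] + level_effect * eff + rng.normal(0, noise, size=n)
        df["other_level"] = np.clip(raw, 0.0, 1.0)
    else:
        df["other_level"] = np.clip(
            df["anchor_level"] + rng.normal(0, noise, size=n), 0.0, 1.0)
    return df
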