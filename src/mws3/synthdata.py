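"""Ground-truth simulators for the deconvolution and CNV pipelines.

``simulate_chip`` emulates one microwell chip: wells receive 0-8 barcoded
beads and 0-3 nuclei; every molecule released by a nucleus is captured by a
uniformly random bead of the same well, so beads co-resident in a well
share molecule identities (17-nt tags in RNA mode, insertion coordinates in
ATAC mode) while beads in different wells share them only by chance.  ATAC
runs add a per-well library of 14-nt spike-in oligos attached to every bead
of the well, and draw fragment positions from a finite pool of accessible
sites so that unrelated nuclei occasionally reuse an insertion — the
background that ranked-Jaccard knee-calling relies on.

``simulate_cnv_study`` emits an expression matrix over tumor /
tumor-adjacent / wild-type cell groups with planted CNV clones: clone cells
multiply the genes of affected cytobands by ``2**amplitude`` under
multiplicative log-normal noise.  ``simulate_barnyard`` plants a known
collision fraction in a two-species mixing experiment.

Every generator is driven by one integer seed through a seed-sequence
spawning scheme, so each well's draws are independent of well order and a
fixed seed reproduces output byte for byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import chipio
from .chipio import ALPHABET, TAGGED_COLUMNS, Whitelist

# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_LETTERS = np.array(list(ALPHABET))


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list:
    if n == 0:
        return []
    codes = rng.integers(0, 4, size=(n, k))
    return ["".join(row) for row in _LETTERS[codes]]


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        choices = [c for c in ALPHABET if c != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def _check_distribution(dist: Mapping[int, float], name: str, max_support: int) -> dict:
    dist = {int(k): float(v) for k, v in dist.items()}
    if any(v < 0 for v in dist.values()) or not np.isclose(sum(dist.values()), 1.0):
        raise ValueError(f"{name} must be a probability distribution")
    if any(k > max_support or k < 0 for k in dist):
        raise ValueError(f"{name} support must lie in 0..{max_support}")
    return dist


# ---------------------------------------------------------------------------
# chip simulation
# ---------------------------------------------------------------------------


@dataclass
class ChipParams:
    """Physical and library parameters of one simulated chip.

    Defaults emulate a 10,000-partition chip loaded so that most occupied
    wells hold fewer than four beads, with 384 preindexes and 3x96 bead
    barcode segments.  ``molecules_per_nucleus`` counts sequenced
    (post-amplification) captures; ``distinct_molecule_fraction`` sets how
    many distinct pre-amplification molecules stand behind them, which
    controls how often two beads of one well capture copies of the same
    molecule.  ``ambient_fraction`` redirects that share of captures to a
    chip-wide ambient pool landing on arbitrary beads.
    """

    n_wells: int = 10_000
    bead_count_distribution: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.05, 1: 0.16, 2: 0.22, 3: 0.20, 4: 0.14, 5: 0.10, 6: 0.06, 7: 0.04, 8: 0.03}
    )
    nuclei_count_distribution: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.30, 1: 0.50, 2: 0.20}
    )
    molecules_per_nucleus: int = 300
    distinct_molecule_fraction: float = 0.5
    ambient_fraction: float = 0.0
    ambient_pool_size: int = 5_000
    n_preindex: int = 384
    spikeins_per_well: int = 5
    species_mix: Optional[Mapping[str, float]] = None
    per_base_error_rate: float = 0.0
    n_genes: int = 200
    accessible_sites: int = 200_000
    n_chromosomes: int = 5
    fragment_length: int = 200
    feature_tag_len: int = 17
    umi_len: int = 6
    spikein_len: int = 14

    def __post_init__(self):
        self.bead_count_distribution = _check_distribution(
            self.bead_count_distribution, "bead_count_distribution", 8
        )
        self.nuclei_count_distribution = _check_distribution(
            self.nuclei_count_distribution, "nuclei_count_distribution", 3
        )
        for name in ("ambient_fraction", "per_base_error_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 < self.distinct_molecule_fraction <= 1):
            raise ValueError("distinct_molecule_fraction must lie in (0, 1]")
        if self.species_mix is not None:
            vals = list(self.species_mix.values())
            if any(v < 0 for v in vals) or not np.isclose(sum(vals), 1.0):
                raise ValueError("species_mix must be a probability distribution")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ChipParams":
        return cls(**payload)


@dataclass
class ChipTruth:
    """Simulator ground truth.

    ``wells`` is one record per well (bead barcodes, nuclei with preindex
    and species).  ``molecules`` is one row per emitted read: its origin
    well, nucleus (-1 for ambient, -2 for spike-in oligo reads) and
    capturing bead, in emission order, so every read traces to exactly one
    truth record.
    """

    wells: list
    molecules: pd.DataFrame
    params: ChipParams

    def n_molecules(self) -> int:
        return len(self.molecules)

    def observed_beads(self) -> set:
        return set(self.molecules["bead_barcode"].unique())

    def same_well_pairs(self, beads: Optional[set] = None) -> set:
        """True unordered same-well bead pairs, optionally restricted to
        beads actually observed in the read output."""
        if beads is None:
            beads = self.observed_beads()
        pairs = set()
        for well in self.wells:
            members = sorted(b for b in well["beads"] if b in beads)
            for a, b in itertools.combinations(members, 2):
                pairs.add((a, b))
        return pairs

    def cell_labels(self) -> pd.DataFrame:
        rows = []
        for well in self.wells:
            for nuc in well["nuclei"]:
                rows.append(
                    {
                        "well": well["well"],
                        "nucleus": nuc["nucleus"],
                        "preindex": nuc["preindex"],
                        "species": nuc["species"],
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        chipio.write_json(
            {
                "n_wells": len(self.wells),
                "n_molecules": int(self.n_molecules()),
                "wells": self.wells,
            },
            path,
        )


@dataclass
class SimulatedChip:
    truth: ChipTruth
    reads: pd.DataFrame
    bead_whitelist: Whitelist
    preindex_whitelist: Whitelist
    assay: str


def _site_to_fragment(site: int, params: ChipParams) -> tuple:
    per_chrom = params.accessible_sites // params.n_chromosomes + 1
    chrom = f"chr{site // per_chrom + 1}"
    start = (site % per_chrom) * 500
    return chrom, start, start + params.fragment_length


def simulate_chip(params: ChipParams, assay: str = "rna", seed: int = 0) -> SimulatedChip:
    """Simulate one chip; identical seeds give byte-identical output."""
    if assay not in ("rna", "atac"):
        raise ValueError(f"unknown assay {assay!r}")
    root = np.random.SeedSequence(seed)
    ss_structure, ss_ambient, ss_wl, *ss_wells = root.spawn(3 + params.n_wells)
    rng = np.random.default_rng(ss_structure)

    bead_wl = chipio.build_bead_whitelist(np.random.default_rng(ss_wl).integers(2**31))
    pre_wl = chipio.build_preindex_whitelist(
        np.random.default_rng(ss_wl.spawn(1)[0]).integers(2**31), n_entries=params.n_preindex
    )
    preindexes = pre_wl.segments[0]

    species_names = sorted(params.species_mix) if params.species_mix else ["_single"]
    species_probs = (
        [params.species_mix[s] for s in species_names] if params.species_mix else [1.0]
    )
    gene_names = {
        s: [f"{s}.g{j:04d}" if s != "_single" else f"g{j:04d}" for j in range(params.n_genes)]
        for s in species_names
    }

    # well structure
    bead_counts = rng.choice(
        list(params.bead_count_distribution),
        size=params.n_wells,
        p=list(params.bead_count_distribution.values()),
    )
    nuclei_counts = rng.choice(
        list(params.nuclei_count_distribution),
        size=params.n_wells,
        p=list(params.nuclei_count_distribution.values()),
    )
    n_beads_total = int(bead_counts.sum())
    seg_n = [len(s) for s in bead_wl.segments]
    combo_ids = rng.choice(int(np.prod(seg_n)), size=n_beads_total, replace=False)
    all_beads = []
    for cid in combo_ids:
        i, rem = divmod(int(cid), seg_n[1] * seg_n[2])
        j, k = divmod(rem, seg_n[2])
        all_beads.append(bead_wl.segments[0][i] + bead_wl.segments[1][j] + bead_wl.segments[2][k])

    wells = []
    cursor = 0
    nucleus_counter = 0
    for w in range(params.n_wells):
        nb = int(bead_counts[w])
        beads = all_beads[cursor : cursor + nb]
        cursor += nb
        nuclei = []
        for _ in range(int(nuclei_counts[w]) if nb else 0):
            sp = species_names[int(rng.choice(len(species_names), p=species_probs))]
            nuclei.append(
                {
                    "nucleus": nucleus_counter,
                    "preindex": preindexes[int(rng.integers(len(preindexes)))],
                    "species": sp,
                }
            )
            nucleus_counter += 1
        wells.append({"well": w, "beads": beads, "nuclei": nuclei})

    # ambient pool (chip-wide free molecules; RNA only, off by default)
    ambient_rng = np.random.default_rng(ss_ambient)
    ambient_tags: list = []
    ambient_genes: list = []
    if params.ambient_fraction > 0 and assay == "rna":
        ambient_tags = _random_kmers(ambient_rng, params.ambient_pool_size, params.feature_tag_len)
        sp_draw = ambient_rng.choice(len(species_names), size=params.ambient_pool_size, p=species_probs)
        gidx = ambient_rng.integers(params.n_genes, size=params.ambient_pool_size)
        ambient_genes = [gene_names[species_names[s]][g] for s, g in zip(sp_draw, gidx)]

    cols: dict[str, list] = {c: [] for c in TAGGED_COLUMNS}
    truth_rows: dict[str, list] = {"well": [], "nucleus": [], "bead_barcode": []}

    def emit(bead, pre, umi="", tag="", chrom="", start="", end="", spike="", anno="", well=-1, nuc=-2):
        cols["bead_barcode"].append(bead)
        cols["preindex"].append(pre)
        cols["umi"].append(umi)
        cols["feature_tag"].append(tag)
        cols["chrom"].append(chrom)
        cols["start"].append(start)
        cols["end"].append(end)
        cols["spikein_tag"].append(spike)
        cols["annotation"].append(anno)
        truth_rows["well"].append(well)
        truth_rows["nucleus"].append(nuc)
        truth_rows["bead_barcode"].append(bead)

    for w, well in enumerate(wells):
        beads = well["beads"]
        if not beads:
            continue
        wrng = np.random.default_rng(ss_wells[w])
        if assay == "atac" and params.spikeins_per_well > 0:
            spikes = _random_kmers(wrng, params.spikeins_per_well, params.spikein_len)
            for bead in beads:
                for sp_tag in spikes:
                    emit(bead, preindexes[0], spike=sp_tag, well=w, nuc=-2)
        for nuc in well["nuclei"]:
            n_reads = params.molecules_per_nucleus
            n_distinct = max(1, round(n_reads * params.distinct_molecule_fraction))
            if assay == "rna":
                pool_tags = _random_kmers(wrng, n_distinct, params.feature_tag_len)
                pool_genes = [
                    gene_names[nuc["species"]][g]
                    for g in wrng.integers(params.n_genes, size=n_distinct)
                ]
            else:
                pool_sites = wrng.integers(params.accessible_sites, size=n_distinct)
            mol_idx = wrng.integers(n_distinct, size=n_reads)
            bead_idx = wrng.integers(len(beads), size=n_reads)
            ambient_mask = (
                wrng.random(n_reads) < params.ambient_fraction
                if ambient_tags
                else np.zeros(n_reads, dtype=bool)
            )
            for r in range(n_reads):
                if ambient_mask[r]:
                    a = int(ambient_rng.integers(len(ambient_tags)))
                    bead = all_beads[int(ambient_rng.integers(len(all_beads)))]
                    emit(
                        bead,
                        nuc["preindex"],
                        umi=ambient_tags[a][: params.umi_len],
                        tag=ambient_tags[a],
                        anno=ambient_genes[a],
                        well=w,
                        nuc=-1,
                    )
                    continue
                bead = beads[int(bead_idx[r])]
                m = int(mol_idx[r])
                if assay == "rna":
                    emit(
                        bead,
                        nuc["preindex"],
                        umi=pool_tags[m][: params.umi_len],
                        tag=pool_tags[m],
                        anno=pool_genes[m],
                        well=w,
                        nuc=nuc["nucleus"],
                    )
                else:
                    chrom, start, end = _site_to_fragment(int(pool_sites[m]), params)
                    emit(
                        bead,
                        nuc["preindex"],
                        chrom=chrom,
                        start=start,
                        end=end,
                        well=w,
                        nuc=nuc["nucleus"],
                    )

    reads = pd.DataFrame(cols)
    for col in ("start", "end"):
        s = reads[col].astype(object)
        s[s == ""] = pd.NA
        reads[col] = pd.to_numeric(s, errors="coerce").astype("Int64")

    if params.per_base_error_rate > 0:
        err_rng = np.random.default_rng(root.spawn(1)[0])
        for col in ("bead_barcode", "preindex", "feature_tag", "spikein_tag", "umi"):
            reads[col] = [
                _mutate(s, err_rng, params.per_base_error_rate) for s in reads[col].astype(object)
            ]

    truth = ChipTruth(wells=wells, molecules=pd.DataFrame(truth_rows), params=params)
    return SimulatedChip(
        truth=truth, reads=reads, bead_whitelist=bead_wl, preindex_whitelist=pre_wl, assay=assay
    )


def chip_reads_to_fastq(reads: pd.DataFrame, umi_len: int = 6):
    """Render RNA tagged reads as a FASTQ mate pair (tag+barcode / preindex).

    The gene annotation travels in the read description (``anno=...``) since
    realistic transcript sequence is out of the simulator's scope.
    """
    rec1, rec2 = [], []
    for i, row in enumerate(reads.itertuples(index=False)):
        if not row.feature_tag:
            continue
        desc = f"anno={row.annotation}" if row.annotation else ""
        rec1.append(chipio.make_fastq_record(f"r{i}", row.feature_tag + row.bead_barcode, desc))
        rec2.append(chipio.make_fastq_record(f"r{i}", row.preindex, desc))
    return rec1, rec2


def pair_metrics(true_pairs: set, predicted_pairs: set) -> dict:
    """Precision/recall of pairwise same-well bead classification."""
    tp = len(true_pairs & predicted_pairs)
    precision = tp / len(predicted_pairs) if predicted_pairs else 1.0
    recall = tp / len(true_pairs) if true_pairs else 1.0
    return {
        "true_pairs": len(true_pairs),
        "predicted_pairs": len(predicted_pairs),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }


# ---------------------------------------------------------------------------
# barnyard simulation
# ---------------------------------------------------------------------------


def simulate_barnyard(
    n_cells: int = 5_000,
    collision_fraction: float = 0.02,
    units_per_cell: int = 1_000,
    contamination: float = 0.01,
    seed: int = 0,
    species: tuple = ("species_a", "species_b"),
) -> pd.DataFrame:
    """Two-species mixing experiment with a planted collision fraction.

    Singlet cells draw their units from their own species with a small
    cross-species ambient contamination; collision cells split units evenly
    between both species.  Returns per-cell unit counts plus truth labels.
    """
    if not (0 <= collision_fraction <= 1):
        raise ValueError("collision_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a, b = species
    is_collision = rng.random(n_cells) < collision_fraction
    own = rng.integers(0, 2, size=n_cells)  # which species a singlet belongs to
    counts_a = np.empty(n_cells, dtype=int)
    counts_b = np.empty(n_cells, dtype=int)
    for i in range(n_cells):
        if is_collision[i]:
            counts_a[i] = rng.binomial(units_per_cell, 0.5)
        else:
            hit = rng.binomial(units_per_cell, 1 - contamination)
            counts_a[i] = hit if own[i] == 0 else units_per_cell - hit
        counts_b[i] = units_per_cell - counts_a[i]
    return pd.DataFrame(
        {
            a: counts_a,
            b: counts_b,
            "true_label": np.where(is_collision, "collision", np.where(own == 0, a, b)),
        },
        index=pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell"),
    )


def simulate_effect_renderings(
    n_cytobands: int = 42,
    methods: Sequence[str] = ("rna", "atac"),
    n_malignant: int = 10,
    n_normal: int = 10,
    noise_sd: float = 0.2,
    effect_sd: float = 1.0,
    seed: int = 0,
) -> tuple:
    """Noisy per-method renderings of one planted cytoband effect vector.

    One true dup/del effect per cytoband is drawn once; each method then
    renders it as a cytoband x pseudobulk matrix where malignant pseudobulks
    carry +effect/2, normal pseudobulks -effect/2, plus independent
    N(0, noise_sd) noise per entry.  Returns ``(true_effects, method_data,
    labels)`` shaped for :func:`mws3.crossmodal.cytoband_effects` (each
    cytoband is its own single-region row).
    """
    rng = np.random.default_rng(seed)
    bands = [f"cb{i:02d}" for i in range(n_cytobands)]
    true_effects = pd.Series(rng.normal(0.0, effect_sd, n_cytobands), index=bands)
    pbs = [f"mal{i}" for i in range(n_malignant)] + [f"nor{i}" for i in range(n_normal)]
    labels = pd.Series(
        ["malignant"] * n_malignant + ["normal"] * n_normal, index=pbs, name="label"
    )
    method_data = {}
    for method in methods:
        signs = np.where(labels == "malignant", 0.5, -0.5)
        values = (
            true_effects.to_numpy()[:, None] * signs[None, :]
            + rng.normal(0.0, noise_sd, size=(n_cytobands, len(pbs)))
        )
        frame = pd.DataFrame(values, index=bands, columns=pbs)
        method_data[method] = (frame, pd.Series(bands, index=bands))
    return true_effects, method_data, labels


# ---------------------------------------------------------------------------
# CNV study simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CloneSpec:
    """One planted clone: affected cytobands, log2 amplitude, prevalence."""

    name: str
    cytobands: tuple
    amplitude: float
    prevalence: Mapping[str, float]

    def __post_init__(self):
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if any(not (0 <= p <= 1) for p in self.prevalence.values()):
            raise ValueError("prevalences must lie in [0, 1]")


@dataclass
class CnvStudyParams:
    """Design of a tumor / adjacent / wild-type CNV study.

    Genes are laid out on ``n_chromosomes`` chromosomes split into
    ``cytobands_per_chromosome`` cytobands each.  Expression is
    ``mu_g * 2**(clone_amplitude + eps)`` with gene baselines ``mu_g``
    log-normal and ``eps ~ N(0, noise_sd)`` in log2 units.  The default
    clone structure plants one dominant clone plus a low-prevalence,
    half-amplitude subclone in both tumor and adjacent tissue — the partial
    CNV burden (subclonal populations, field effects) that real tumors and
    their margins carry.
    """

    n_genes: int = 2_000
    n_chromosomes: int = 5
    cytobands_per_chromosome: int = 4
    group_cells: Mapping[str, int] = field(
        default_factory=lambda: {"tumor": 1800, "adjacent": 1200, "normal": 600}
    )
    clones: Sequence[CloneSpec] = ()
    noise_sd: float = 0.1
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.0

    def __post_init__(self):
        if not self.clones:
            self.clones = default_clones()
        bands = set(self.cytoband_names())
        for clone in self.clones:
            missing = [c for c in clone.cytobands if c not in bands]
            if missing:
                raise ValueError(f"clone {clone.name} references unknown cytobands {missing}")
            total = {}
            for g, p in clone.prevalence.items():
                total[g] = total.get(g, 0) + p
        for group in self.group_cells:
            s = sum(c.prevalence.get(group, 0.0) for c in self.clones)
            if s > 1:
                raise ValueError(f"clone prevalences in group {group!r} exceed 1")

    def cytoband_names(self) -> list:
        return [
            f"chr{c + 1}.b{b + 1}"
            for c in range(self.n_chromosomes)
            for b in range(self.cytobands_per_chromosome)
        ]

    def gene_table(self) -> pd.DataFrame:
        """Gene positions and cytoband assignment, genome-ordered."""
        genes_per_chrom = self.n_genes // self.n_chromosomes
        rows = []
        for i in range(self.n_genes):
            c = min(i // genes_per_chrom, self.n_chromosomes - 1)
            pos_in_chrom = i - c * genes_per_chrom
            band = min(
                pos_in_chrom * self.cytobands_per_chromosome // genes_per_chrom,
                self.cytobands_per_chromosome - 1,
            )
            start = pos_in_chrom * 10_000
            rows.append(
                {
                    "gene": f"gene{i:05d}",
                    "chrom": f"chr{c + 1}",
                    "start": start,
                    "end": start + 1_000,
                    "cytoband": f"chr{c + 1}.b{band + 1}",
                }
            )
        return pd.DataFrame(rows).set_index("gene")

    @classmethod
    def default(cls, amplitude: float = 0.3, noise_sd: float = 0.1, **kw) -> "CnvStudyParams":
        """Default design with the main clone at ``amplitude`` and a
        half-amplitude subclone; 2 of 20 cytobands (10%) are affected."""
        clones = (
            CloneSpec(
                name="main",
                cytobands=("chr1.b1", "chr3.b2"),
                amplitude=amplitude,
                prevalence={"tumor": 0.72, "adjacent": 0.08, "normal": 0.0},
            ),
            # distinct low-burden subclonal lineages, each on its own cytoband
            CloneSpec(
                name="sub1",
                cytobands=("chr2.b1",),
                amplitude=amplitude / 2,
                prevalence={"tumor": 0.01, "adjacent": 0.01, "normal": 0.0},
            ),
            CloneSpec(
                name="sub2",
                cytobands=("chr4.b3",),
                amplitude=amplitude / 2,
                prevalence={"tumor": 0.01, "adjacent": 0.01, "normal": 0.0},
            ),
            CloneSpec(
                name="sub3",
                cytobands=("chr5.b2",),
                amplitude=amplitude / 2,
                prevalence={"tumor": 0.01, "adjacent": 0.0, "normal": 0.0},
            ),
            CloneSpec(
                name="sub4",
                cytobands=("chr2.b4",),
                amplitude=amplitude / 2,
                prevalence={"tumor": 0.01, "adjacent": 0.0, "normal": 0.0},
            ),
        )
        return cls(clones=clones, noise_sd=noise_sd, **kw)


def simulate_cnv_study(params: CnvStudyParams, seed: int = 0) -> tuple:
    """Expression matrix with planted clones.

    Returns ``(matrix, gene_meta, cell_meta)``: genes x cells expression
    values, the gene/cytoband table, and per-cell truth (group, clone,
    malignant flag).  A cell is malignant iff it carries any clone.
    """
    rng = np.random.default_rng(seed)
    gene_meta = params.gene_table()
    mu = 2.0 ** rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, params.n_genes)

    clone_masks = {}
    for clone in params.clones:
        clone_masks[clone.name] = gene_meta["cytoband"].isin(clone.cytobands).to_numpy()

    cells, groups, clone_of = [], [], []
    for group in params.group_cells:
        n = params.group_cells[group]
        probs = [c.prevalence.get(group, 0.0) for c in params.clones]
        probs = [1 - sum(probs)] + probs
        draws = rng.choice(len(probs), size=n, p=probs)
        for i, d in enumerate(draws):
            cells.append(f"{group}.c{i:05d}")
            groups.append(group)
            clone_of.append(None if d == 0 else params.clones[d - 1].name)

    n_cells = len(cells)
    log2_shift = np.zeros((params.n_genes, n_cells))
    for j, cname in enumerate(clone_of):
        if cname is None:
            continue
        clone = next(c for c in params.clones if c.name == cname)
        log2_shift[clone_masks[cname], j] += clone.amplitude
    if params.noise_sd > 0:
        log2_shift += rng.normal(0.0, params.noise_sd, size=(params.n_genes, n_cells))
    matrix = pd.DataFrame(
        mu[:, None] * 2.0**log2_shift, index=gene_meta.index, columns=cells
    )
    cell_meta = pd.DataFrame(
        {
            "group": groups,
            "clone": [c if c is not None else "" for c in clone_of],
            "malignant": [c is not None for c in clone_of],
        },
        index=pd.Index(cells, name="cell"),
    )
    return matrix, gene_meta, cell_meta
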