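"""Synthetic divergent-transcription dataset with planted ground truth.

The generator emits a coherent bundle — genome FASTA, NDR peak calls, gene
annotation, stranded per-base nascent-RNA 5'-end bedGraphs, histone-mark
signal tracks with matching peak calls, an accessibility track, and a truth
table — in exactly the formats the pipeline consumes.  Planted structure:

* each element's true forward/reverse initiation log2-ratio is *caused* by
  two latent asymmetries — core-promoter sequence strength s and nucleosome
  mark asymmetry a — through component-specific linear forms
  ratio = b0_k + b_seq_k*s + b_chrom_k*a + noise_k, giving a two-component
  mixture (directionally balanced, sequence-driven, vs. skewed,
  chromatin-driven) that a mixture of linear regressions can recover;
* forward totals are negative-binomial, reverse totals are the forward
  total scaled by 2^(-ratio) with Poisson noise;
* per-base TSS profiles are Dirichlet-multinomial with a per-element
  concentration that controls the entropy (DP) of the profile;
* the reverse TSS sits upstream of the forward TSS (divergent geometry);
* TATA-like (-30) and Inr-like (+1) consensus motifs are planted on each
  strand with per-base degeneracy that falls with that strand's share of s,
  making core-promoter sequence scores informative;
* mark tracks follow a known per-bin state path with Gaussian emissions;
  the +1/-1-nucleosome H3K4me3 asymmetry encodes a, making H3K4me3 flank
  ratios informative;
* gene bodies carry low-rate background 5'-ends at a configurable
  contamination rate (default 0: clean study conditions).

Elements live in fixed non-overlapping slots so no element's gene body,
mark flanks or downstream control windows reach a neighbour.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_models import reverse_complement

BASES = "ACGT"

# planted chromatin states (per 10 bp bin); background bins carry no state
STATE_PROM_UP = 0  # -1 nucleosome flank (reverse direction)
STATE_PROM_CORE = 1  # promoter NDR core
STATE_PROM_DOWN = 2  # +1 nucleosome flank (forward direction)
STATE_ENH_FLANK = 3  # enhancer flanking nucleosomes
STATE_ENH_CORE = 4  # enhancer NDR core
N_TRUE_STATES = 5

MARKS = ("h3k27ac", "h3k4me1", "h3k4me3")

TATA_MOTIF = "TATAAA"  # planted so that it starts at TSS-30
TATA_OFFSET = -30
INR_MOTIF = "TCAGTT"  # Inr-like; the A sits on the TSS (+1) base
INR_OFFSET = -2


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle (defaults are the ones the
    acceptance walkthrough runs)."""

    n_promoters: int = 600
    n_enhancers: int = 200
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 500_000 for i in range(1, 5)}
    )
    gc_content: float = 0.40
    slot_size: int = 2400
    flank_len: int = 500  # mark-covered nucleosomal flank per side
    peak_width_range: tuple[int, int] = (150, 250)
    tss_spacing_range: tuple[int, int] = (70, 140)  # reverse-to-forward TSS distance
    gene_length: int = 1200
    # structural directionality model, per component (balanced, skewed):
    # the true log2-ratio is caused by a latent core-promoter strength
    # asymmetry s ~ N(0, seq_strength_sd) and a latent nucleosome/mark
    # asymmetry a ~ N(asym_mean_k, chrom_asym_sd):
    #   ratio = b0_k + b_seq_k * s + b_chrom_k * a + noise_k
    # so each component is Gaussian in the ratio, balanced initiation is
    # sequence-driven and skewed initiation chromatin-driven
    promoter_weights: tuple[float, float] = (0.5, 0.5)
    enhancer_weights: tuple[float, float] = (0.85, 0.15)
    mixture_intercepts: tuple[float, float] = (0.4, 3.8)
    seq_coefs: tuple[float, float] = (0.9, 0.2)
    chrom_coefs: tuple[float, float] = (0.15, 1.0)
    ratio_noise_sds: tuple[float, float] = (0.35, 0.45)
    chrom_asym_means: tuple[float, float] = (0.0, 1.5)
    chrom_asym_sd: float = 1.0
    seq_strength_sd: float = 1.0
    # sequencing depth: negative-binomial forward totals
    depth_mean: float = 300.0
    nb_dispersion: float = 0.3
    # TSS profile shape: Dirichlet concentration ~ 10**U(log10 range)
    profile_halfwidth: int = 30
    concentration_range: tuple[float, float] = (2.0, 200.0)
    profile_decay: float = 4.0
    # motif planting: motifs are planted on each strand with probability
    # ``motif_plant_prob``; their per-base degeneracy (mutation rate) falls
    # with the strand's share of the latent sequence strength s, so planted
    # motif *strength* carries the sequence signal
    motif_plant_prob: float = 0.9
    base_mutation: float = 0.2
    mutation_coupling: float = 0.15
    tata_jitter: int = 2  # TATA position jitter (bp, uniform either side)
    # chromatin emissions (log scale): the H3K4me3 flank *level* tracks total
    # activity; the down-vs-up *asymmetry* is chrom_asym_scale * a
    k4me3_base: float = 1.4
    k4me3_level_coupling: float = 0.2
    chrom_asym_scale: float = 0.5
    emission_sd: float = 0.4
    # gene-body 5'-end background per base
    contamination_rate: float = 0.0
    bin_size: int = 10


@dataclass
class SimBundle:
    """Paths of the emitted files plus the in-memory truth tables."""

    out_dir: str
    paths: dict[str, str]
    truth: pd.DataFrame
    truth_states: pd.DataFrame
    config: SimConfig


def _plant(genome: dict[str, np.ndarray], chrom: str, tss: int, strand: str,
           motif: str, offset: int, rng: np.random.Generator,
           mutation_rate: float = 0.0) -> None:
    """Write ``motif`` so it reads 5'->3' on ``strand`` starting at ``offset``
    relative to the TSS, with per-base degeneracy at ``mutation_rate``."""
    codes = np.array([BASES.index(b) for b in motif], dtype=np.uint8)
    if mutation_rate > 0:
        mutate = rng.random(len(codes)) < mutation_rate
        codes = np.where(mutate, rng.integers(0, 4, len(codes)).astype(np.uint8), codes)
    if strand == "+":
        start = tss + offset
        genome[chrom][start : start + len(codes)] = codes
    else:
        rc = reverse_complement("".join(BASES[c] for c in codes))
        codes = np.array([BASES.index(b) for b in rc], dtype=np.uint8)
        end = tss - offset + 1
        genome[chrom][end - len(codes) : end] = codes


def _oriented(slot_start: int, slot_size: int, local: int, strand: str) -> int:
    """Map an oriented local coordinate into genomic space."""
    if strand == "+":
        return slot_start + local
    return slot_start + slot_size - 1 - local


def _profile_counts(
    rng: np.random.Generator, total: int, halfwidth: int, decay: float, conc: float
) -> np.ndarray:
    offsets = np.arange(-halfwidth, halfwidth + 1)
    template = np.exp(-np.abs(offsets) / decay)
    template /= template.sum()
    p = rng.dirichlet(conc * template)
    return rng.multinomial(total, p)


def generate(seed: int, config: SimConfig | None = None, out_dir: str = ".") -> SimBundle:
    """Generate the full synthetic bundle under ``out_dir``.

    All randomness flows from a single ``numpy`` generator seeded with
    ``seed``; identical seeds give byte-identical files.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)

    n_elements = cfg.n_promoters + cfg.n_enhancers
    slots_per_chrom = {c: size // cfg.slot_size for c, size in cfg.chrom_sizes.items()}
    all_slots = [
        (chrom, i * cfg.slot_size)
        for chrom in sorted(cfg.chrom_sizes)
        for i in range(slots_per_chrom[chrom])
    ]
    if n_elements > len(all_slots):
        raise ValueError(
            f"{n_elements} elements do not fit in {len(all_slots)} genome slots"
        )
    slot_idx = rng.permutation(len(all_slots))[:n_elements]

    # genome: i.i.d. bases at the configured GC content
    p = np.array(
        [
            (1 - cfg.gc_content) / 2,
            cfg.gc_content / 2,
            cfg.gc_content / 2,
            (1 - cfg.gc_content) / 2,
        ]
    )
    genome = {
        chrom: rng.choice(4, size=size, p=p).astype(np.uint8)
        for chrom, size in sorted(cfg.chrom_sizes.items())
    }

    plus: dict[str, dict[int, int]] = {c: {} for c in cfg.chrom_sizes}
    minus: dict[str, dict[int, int]] = {c: {} for c in cfg.chrom_sizes}

    def add_counts(chrom: str, strand: str, tss: int, counts: np.ndarray) -> None:
        store = plus[chrom] if strand == "+" else minus[chrom]
        offsets = np.arange(-cfg.profile_halfwidth, cfg.profile_halfwidth + 1)
        for off, n in zip(offsets.tolist(), counts.tolist()):
            if n == 0:
                continue
            pos = tss + off if strand == "+" else tss - off
            store[pos] = store.get(pos, 0) + n

    # per-bin state path and mark emission means, built element by element
    n_bins = {c: size // cfg.bin_size for c, size in cfg.chrom_sizes.items()}
    state_path = {c: np.full(n, -1, dtype=np.int8) for c, n in n_bins.items()}
    mark_z = {
        mark: {c: np.zeros(n) for c, n in n_bins.items()} for mark in MARKS
    }
    mark_peak_rows: dict[str, list[tuple[str, int, int]]] = {m: [] for m in MARKS}
    atac_z = {c: np.zeros(n) for c, n in n_bins.items()}

    peak_rows: list[tuple[str, int, int, str]] = []
    gene_rows: list[tuple[str, int, int, str, str]] = []
    truth_rows: list[dict] = []

    w_lo, w_hi = cfg.peak_width_range
    d_lo, d_hi = cfg.tss_spacing_range
    fl = cfg.flank_len

    for eid in range(n_elements):
        is_promoter = eid < cfg.n_promoters
        chrom, slot_start = all_slots[slot_idx[eid]]
        strand = "+" if rng.random() < 0.5 else "-"
        width = int(rng.integers(w_lo, w_hi + 1))
        d = int(rng.integers(d_lo, min(d_hi, width - 80) + 1))

        # oriented local layout: [200, 200+fl) upstream flank, then the NDR
        peak_lo_local = 200 + fl
        rev_local = peak_lo_local + (width - d) // 2
        fwd_local = rev_local + d
        locs = [
            _oriented(slot_start, cfg.slot_size, peak_lo_local, strand),
            _oriented(slot_start, cfg.slot_size, peak_lo_local + width - 1, strand),
        ]
        peak_start, peak_end = min(locs), max(locs) + 1
        fwd_tss = _oriented(slot_start, cfg.slot_size, fwd_local, strand)
        rev_tss = _oriented(slot_start, cfg.slot_size, rev_local, strand)
        rev_strand = "-" if strand == "+" else "+"

        # directionality truth: latent sequence and chromatin asymmetries
        # cause the ratio, with component-specific coefficients
        weights = cfg.promoter_weights if is_promoter else cfg.enhancer_weights
        comp = int(rng.random() < weights[1])  # 0 balanced, 1 skewed
        seq_strength = float(rng.normal(0.0, cfg.seq_strength_sd))
        chrom_asym = float(rng.normal(cfg.chrom_asym_means[comp], cfg.chrom_asym_sd))
        true_ratio = float(
            cfg.mixture_intercepts[comp]
            + cfg.seq_coefs[comp] * seq_strength
            + cfg.chrom_coefs[comp] * chrom_asym
            + rng.normal(0.0, cfg.ratio_noise_sds[comp])
        )
        if not is_promoter and true_ratio < 0:
            # enhancer forward = higher-count strand: relabel the strands,
            # flipping the latent asymmetries with the ratio
            true_ratio, seq_strength, chrom_asym = -true_ratio, -seq_strength, -chrom_asym
        r = 1.0 / cfg.nb_dispersion
        fwd_total = int(rng.negative_binomial(r, r / (r + cfg.depth_mean)))
        rev_total = int(rng.poisson(fwd_total * 2.0 ** (-true_ratio)))

        conc_fwd = 10 ** rng.uniform(*np.log10(cfg.concentration_range))
        conc_rev = 10 ** rng.uniform(*np.log10(cfg.concentration_range))
        if fwd_total > 0:
            add_counts(
                chrom, strand, fwd_tss,
                _profile_counts(rng, fwd_total, cfg.profile_halfwidth,
                                cfg.profile_decay, conc_fwd),
            )
        if rev_total > 0:
            add_counts(
                chrom, rev_strand, rev_tss,
                _profile_counts(rng, rev_total, cfg.profile_halfwidth,
                                cfg.profile_decay, conc_rev),
            )

        # core-promoter motifs: degeneracy falls with each strand's share of
        # the latent sequence-strength asymmetry
        motif_fwd = rng.random() < cfg.motif_plant_prob
        motif_rev = rng.random() < cfg.motif_plant_prob
        mut_fwd = float(
            np.clip(cfg.base_mutation - cfg.mutation_coupling * seq_strength / 2, 0.02, 0.45)
        )
        mut_rev = float(
            np.clip(cfg.base_mutation + cfg.mutation_coupling * seq_strength / 2, 0.02, 0.45)
        )
        if motif_fwd:
            jit = int(rng.integers(-cfg.tata_jitter, cfg.tata_jitter + 1))
            _plant(genome, chrom, fwd_tss, strand, TATA_MOTIF, TATA_OFFSET + jit, rng, mut_fwd)
            _plant(genome, chrom, fwd_tss, strand, INR_MOTIF, INR_OFFSET, rng, mut_fwd)
        if motif_rev:
            jit = int(rng.integers(-cfg.tata_jitter, cfg.tata_jitter + 1))
            _plant(genome, chrom, rev_tss, rev_strand, TATA_MOTIF, TATA_OFFSET + jit, rng, mut_rev)
            _plant(genome, chrom, rev_tss, rev_strand, INR_MOTIF, INR_OFFSET, rng, mut_rev)

        # chromatin: state path and mark emission means over the element span
        up_lo = _min_max(slot_start, cfg.slot_size, 200, 200 + fl - 1, strand)
        down_lo = _min_max(
            slot_start, cfg.slot_size, peak_lo_local + width,
            peak_lo_local + width + fl - 1, strand,
        )
        core_span = (peak_start, peak_end)
        element_span = (
            min(up_lo[0], down_lo[0], core_span[0]),
            max(up_lo[1], down_lo[1], core_span[1]),
        )

        level = cfg.k4me3_base + cfg.k4me3_level_coupling * (
            np.log2(fwd_total + rev_total + 1) - 8
        )
        asym = cfg.chrom_asym_scale * chrom_asym
        k4_down = max(0.1, level + asym / 2)
        k4_up = max(0.1, level - asym / 2)
        if is_promoter:
            spans = {
                STATE_PROM_UP: up_lo,
                STATE_PROM_CORE: core_span,
                STATE_PROM_DOWN: down_lo,
            }
            z_by_state = {
                STATE_PROM_UP: {"h3k27ac": 1.0, "h3k4me1": 0.0, "h3k4me3": k4_up},
                STATE_PROM_CORE: {"h3k27ac": 0.6, "h3k4me1": 0.0, "h3k4me3": 0.8},
                STATE_PROM_DOWN: {"h3k27ac": 2.0, "h3k4me1": 0.0, "h3k4me3": k4_down},
            }
            active_marks = ("h3k27ac", "h3k4me3")
        else:
            spans = {
                STATE_ENH_FLANK: up_lo,
                STATE_ENH_CORE: core_span,
                # reuse the flank state downstream: enhancer flanks are symmetric
            }
            z_by_state = {
                STATE_ENH_FLANK: {"h3k27ac": 1.5, "h3k4me1": 2.0, "h3k4me3": 0.0},
                STATE_ENH_CORE: {"h3k27ac": 0.6, "h3k4me1": 0.8, "h3k4me3": 0.0},
            }
            active_marks = ("h3k27ac", "h3k4me1")
        bs = cfg.bin_size
        for state, (lo, hi) in list(spans.items()) + (
            [(STATE_ENH_FLANK, down_lo)] if not is_promoter else []
        ):
            b0, b1 = lo // bs, (hi - 1) // bs + 1
            state_path[chrom][b0:b1] = state
            nb = b1 - b0
            for mark in MARKS:
                mu = z_by_state[state][mark]
                if mu > 0:
                    mark_z[mark][chrom][b0:b1] = np.maximum(
                        rng.normal(mu, cfg.emission_sd, size=nb), 0.0
                    )
        for mark in active_marks:
            mark_peak_rows[mark].append((chrom, element_span[0], element_span[1]))

        # accessibility bump over the NDR
        b0, b1 = peak_start // bs, (peak_end - 1) // bs + 1
        atac_z[chrom][b0:b1] = np.maximum(rng.normal(2.0, 0.3, size=b1 - b0), 0.2)

        peak_rows.append((chrom, peak_start, peak_end, f"elem{eid}"))
        if is_promoter:
            if strand == "+":
                gene_rows.append((chrom, fwd_tss, fwd_tss + cfg.gene_length, f"gene{eid}", "+"))
            else:
                gene_rows.append((chrom, fwd_tss - cfg.gene_length + 1, fwd_tss + 1, f"gene{eid}", "-"))
            # gene-body 5'-end contamination downstream of the peak
            if cfg.contamination_rate > 0:
                if strand == "+":
                    body = np.arange(peak_end, fwd_tss + cfg.gene_length)
                else:
                    body = np.arange(fwd_tss - cfg.gene_length + 1, peak_start)
                noise = rng.poisson(cfg.contamination_rate, size=body.size)
                store = plus[chrom] if strand == "+" else minus[chrom]
                for pos, n in zip(body[noise > 0].tolist(), noise[noise > 0].tolist()):
                    store[pos] = store.get(pos, 0) + int(n)

        truth_rows.append(
            {
                "element_id": f"elem{eid}",
                "class": "promoter" if is_promoter else "enhancer",
                "chrom": chrom,
                "peak_start": peak_start,
                "peak_end": peak_end,
                "forward_strand": strand,
                "fwd_tss": fwd_tss,
                "rev_tss": rev_tss,
                "component": "skewed" if comp == 1 else "balanced",
                "true_ratio": true_ratio,
                "seq_strength": seq_strength,
                "chrom_asym": chrom_asym,
                "fwd_total": fwd_total,
                "rev_total": rev_total,
                "realized_log_ratio": float(np.log2((fwd_total + 1) / (rev_total + 1))),
                "divergent": bool(fwd_total >= 1 and rev_total >= 1),
                "conc_fwd": conc_fwd,
                "conc_rev": conc_rev,
                "motif_fwd": bool(motif_fwd),
                "motif_rev": bool(motif_rev),
            }
        )

    truth = pd.DataFrame(truth_rows)
    paths = _write_bundle(
        out_dir, cfg, genome, plus, minus, mark_z, mark_peak_rows, atac_z,
        peak_rows, gene_rows, truth, state_path,
    )
    state_rows = []
    for chrom in sorted(state_path):
        labelled = np.flatnonzero(state_path[chrom] >= 0)
        for b in labelled.tolist():
            state_rows.append(
                {"chrom": chrom, "bin_start": b * cfg.bin_size,
                 "state": int(state_path[chrom][b])}
            )
    truth_states = pd.DataFrame(state_rows)
    truth_states.to_csv(paths["truth_states"], sep="\t", index=False)
    return SimBundle(out_dir=out_dir, paths=paths, truth=truth,
                     truth_states=truth_states, config=cfg)


def _min_max(slot_start: int, slot_size: int, lo_local: int, hi_local: int,
             strand: str) -> tuple[int, int]:
    a = _oriented(slot_start, slot_size, lo_local, strand)
    b = _oriented(slot_start, slot_size, hi_local, strand)
    return (min(a, b), max(a, b) + 1)


def _write_bundle(
    out_dir, cfg, genome, plus, minus, mark_z, mark_peak_rows, atac_z,
    peak_rows, gene_rows, truth, state_path,
) -> dict[str, str]:
    from .genomic_io import StrandedTssTrack, write_bedgraph_dense, write_stranded_bedgraph

    paths: dict[str, str] = {}

    def path_of(name: str, fname: str) -> str:
        paths[name] = os.path.join(out_dir, fname)
        return paths[name]

    base_lut = np.array(list("ACGT"))
    with open(path_of("genome", "genome.fa"), "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = "".join(base_lut[genome[chrom]])
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    with open(path_of("peaks", "peaks.bed"), "w") as fh:
        for chrom, start, end, name in sorted(peak_rows):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t.\n")

    with open(path_of("genes", "genes.bed"), "w") as fh:
        for chrom, start, end, name, strand in sorted(gene_rows):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")

    track = StrandedTssTrack.from_dicts(plus, minus)
    write_stranded_bedgraph(
        track, path_of("procap_plus", "procap_plus.bedgraph"),
        path_of("procap_minus", "procap_minus.bedgraph"),
    )

    bs = cfg.bin_size
    for mark in mark_z:
        signal = {
            chrom: np.repeat(np.expm1(z), bs) for chrom, z in mark_z[mark].items()
        }
        write_bedgraph_dense(signal, path_of(mark, f"{mark}.bedgraph"), step=bs)
        with open(path_of(f"{mark}_peaks", f"{mark}_peaks.bed"), "w") as fh:
            for chrom, start, end in sorted(mark_peak_rows[mark]):
                fh.write(f"{chrom}\t{start}\t{end}\n")
    atac_signal = {chrom: np.repeat(np.expm1(z), bs) for chrom, z in atac_z.items()}
    write_bedgraph_dense(atac_signal, path_of("atac", "atac.bedgraph"), step=bs)

    truth.to_csv(path_of("truth", "truth.tsv"), sep="\t", index=False)
    path_of("truth_states", "truth_states.tsv")
    with open(path_of("chrom_sizes", "chrom.sizes"), "w") as fh:
        for chrom, size in sorted(cfg.chrom_sizes.items()):
            fh.write(f"{chrom}\t{size}\n")
    return paths


# ---------------------------------------------------------------------------
# Scoring inferred outputs against the planted truth


def truth_report(
    truth: pd.DataFrame,
    records: pd.DataFrame | None = None,
    predictions: pd.DataFrame | None = None,
    extension: int = 75,
) -> dict[str, float]:
    """Recovery metrics for inferred outputs against generator truth.

    ``records`` is the per-peak table from the TSS-calling stage (matched to
    truth elements by the extended peak interval); ``predictions`` must carry
    ``element_id``, ``predicted_class`` and ``predicted_ratio`` columns from
    the directionality model.  Raises on element-id mismatches.
    """
    from scipy.stats import spearmanr
    from sklearn.metrics import adjusted_rand_score

    out: dict[str, float] = {}
    if records is not None:
        key = records.set_index(["chrom", "start"])
        matched = 0
        set_b_hits = 0
        divergent = truth[truth["divergent"]]
        est_ratio, true_ratio = [], []
        for row in truth.itertuples():
            k = (row.chrom, row.peak_start - extension)
            if k not in key.index:
                raise ValueError(f"element {row.element_id} missing from records")
            rec = key.loc[k]
            matched += 1
            est_ratio.append(rec["log_ratio"])
            true_ratio.append(row.realized_log_ratio)
            if row.divergent and rec["set_label"] == "B":
                set_b_hits += 1
        out["n_matched"] = matched
        out["set_b_recall"] = set_b_hits / max(len(divergent), 1)
        out["ratio_spearman"] = float(spearmanr(est_ratio, true_ratio).statistic)
    if predictions is not None:
        merged = truth.merge(predictions, on="element_id", validate="one_to_one")
        if len(merged) != len(predictions):
            raise ValueError("prediction element ids do not match truth")
        out["component_ari"] = float(
            adjusted_rand_score(merged["component"], merged["predicted_class"])
        )
        out["predicted_ratio_pearson"] = float(
            np.corrcoef(merged["predicted_ratio"], merged["realized_log_ratio"])[0, 1]
        )
    return out
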