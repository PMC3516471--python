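"""Synthetic probe-level microarray data with known ground truth.

The generator emulates the design of a single-channel time-course array
experiment on an iron-depleted cyanobacterial culture: six time points
(0, 3, 12, 24, 48, 72 h), two replicate hybridizations per time point,
replicated probes per transcript, a pool of low-intensity control spots
(empty/spike-in positions whose signal is pure nonspecific hybridization),
and a transcript universe mixing mRNAs, cis-antisense RNAs (asRNAs) and
intergenic small RNAs (sRNAs).

Planted structure, all recorded in a :class:`TruthTable`:

* four temporal response archetypes (monotone up/down, transient up/down
  peaking at 12 h) assigned to a configurable fraction of transcripts;
* asRNA-mRNA coupling classes: class I asRNAs share the latent profile of
  their sense partner (r -> +1 as noise -> 0), class III carry its negation
  (r -> -1), class II an independent latent profile;
* marker-tracking sRNAs whose latent profile is the marker gene's profile
  (or its negation), emulating sRNAs co-regulated with *isiA*;
* gene-set categories, some enriched in same-direction responders;
* a block of transcripts planted below the detection floor, which the
  expression filter should flag as unexpressed.

Intensities are generated as ``2**(baseline + true_log2fc + array_effect +
eps)`` with ``eps ~ N(0, noise_sd)`` — the conventional multiplicative
log-normal microarray error model.  All randomness flows from
``SimulationConfig.seed``; identical configs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as fio

DEFAULT_TIMEPOINTS = (0.0, 3.0, 12.0, 24.0, 48.0, 72.0)

ARCHETYPES = ("flat", "monotone-down", "monotone-up", "transient-up", "transient-down")
PAIR_CLASSES = ("I", "II", "III")


class ConfigError(ValueError):
    """A SimulationConfig field is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults mirror the emulated experimental design: 6 time points with two
    replicate arrays each, duplicated probes, log2-scale noise of 0.25 and a
    planted response amplitude of 2 (a 4-fold change at the profile peak).
    """

    seed: int = 0
    n_mrna: int = 500
    n_asrna: int = 60
    n_srna: int = 120
    n_control: int = 200
    n_unexpressed: int = 50
    probes_per_transcript: int = 2
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    arrays_per_timepoint: int = 2
    noise_sd: float = 0.25
    effect_size: float = 2.0
    fraction_responders: float = 0.2
    pair_class_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    n_marker_srnas: int = 6
    n_categories: int = 10
    category_size: int = 25
    n_enriched_categories: int = 2
    detection_floor: float = 128.0
    array_effect_sd: float = 0.0
    baseline_log2_range: tuple[float, float] = (9.0, 14.0)
    control_log2_mean: float = 6.0
    control_log2_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "n_mrna",
            "n_asrna",
            "n_srna",
            "n_control",
            "probes_per_transcript",
            "arrays_per_timepoint",
            "n_categories",
            "category_size",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        for name in ("n_unexpressed", "n_marker_srnas", "n_enriched_categories"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.fraction_responders <= 1.0:
            raise ConfigError("fraction_responders must be in [0, 1]")
        mix = self.pair_class_mix
        if len(mix) != 3 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigError("pair_class_mix must be 3 proportions summing to 1")
        tp = self.timepoints
        if len(tp) < 2 or tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigError("timepoints must be strictly increasing and start at 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.detection_floor <= 0:
            raise ConfigError("detection_floor must be > 0")


def archetype_shape(archetype: str, timepoints=DEFAULT_TIMEPOINTS) -> np.ndarray:
    """Unit-amplitude latent temporal shape of an archetype.

    Monotone shapes follow a saturating log-time ramp; transient shapes peak
    (or dip) at 12 h and relax afterwards.  The reference point (0 h) is
    always 0.
    """
    t = np.asarray(timepoints, dtype=float)
    if archetype == "flat":
        return np.zeros_like(t)
    ramp = np.log1p(t) / np.log1p(t[-1])
    if archetype == "monotone-up":
        return ramp
    if archetype == "monotone-down":
        return -ramp
    # transient: rises to 1 at 12 h, decays to ~0.1 at 72 h
    peak = 12.0
    trans = np.where(
        t <= peak,
        t / peak,
        0.1 + 0.9 * np.exp(-(t - peak) / 20.0),
    )
    trans[t == 0] = 0.0
    if archetype == "transient-up":
        return trans
    if archetype == "transient-down":
        return -trans
    raise ValueError(f"unknown archetype {archetype!r}")


def plant_pair(
    sense_latent: np.ndarray,
    pair_class: str,
    noise_sd: float,
    rng: np.random.Generator | None = None,
    independent_latent: np.ndarray | None = None,
) -> np.ndarray:
    """Latent antisense log2FC profile coupled to a sense profile.

    Class I copies the sense latent profile, class III its negation, class II
    uses an independent latent profile (provided, or drawn as a random
    non-flat archetype of the same amplitude).  Gaussian noise of
    ``noise_sd`` is added pointwise; as ``noise_sd -> 0`` the realized
    Pearson correlation with the sense profile tends to +1 (I) and -1 (III).
    """
    sense_latent = np.asarray(sense_latent, dtype=float)
    if len(sense_latent) < 3:
        raise ValueError("sense profile needs at least 3 post-treatment points")
    rng = rng if rng is not None else np.random.default_rng(0)
    if pair_class == "I":
        latent = sense_latent.copy()
    elif pair_class == "III":
        latent = -sense_latent
    elif pair_class == "II":
        if independent_latent is None:
            independent_latent = _orthogonal_latent(sense_latent, rng)
        latent = np.asarray(independent_latent, dtype=float)
    else:
        raise ValueError(f"unknown pair class {pair_class!r}")
    if noise_sd > 0:
        latent = latent + rng.normal(0.0, noise_sd, size=latent.shape)
    return latent


def _orthogonal_latent(sense: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random latent profile uncorrelated (Pearson r = 0) with the sense
    profile, scaled to the sense amplitude.

    If the sense profile starts with the reference value 0, that point is
    kept at 0 and orthogonalization runs over the remaining (post-treatment)
    points, matching how pair correlations are computed downstream.
    """
    has_ref = sense[0] == 0.0
    post = sense[1:] if has_ref else sense
    for _ in range(10):
        z = rng.normal(size=post.shape)
        zc = z - z.mean()
        sc = post - post.mean()
        denom = float(sc @ sc)
        if denom > 0:
            zc = zc - (zc @ sc) / denom * sc
        peak = float(np.max(np.abs(zc)))
        if peak > 1e-8:
            amp = float(np.max(np.abs(post))) or 1.0
            zc = zc * (amp / peak)
            return np.concatenate([[0.0], zc]) if has_ref else zc
    raise RuntimeError("failed to draw an independent latent profile")


@dataclass
class TruthTable:
    """Ground truth written alongside every synthetic dataset."""

    transcripts: pd.DataFrame  # transcript_id, class, archetype, expressed, baseline_log2, true_fc_*
    pairs: pd.DataFrame  # antisense_id, sense_id, pair_class
    srnas: pd.DataFrame  # srna_id, marker_sign (+1/-1/0)
    categories: pd.DataFrame  # set_id, enriched

    def write(self, outdir: str | os.PathLike) -> None:
        fio.ensure_dir(outdir)
        fio.write_tsv(self.transcripts, os.path.join(outdir, "truth_transcripts.tsv"))
        fio.write_tsv(self.pairs, os.path.join(outdir, "truth_pairs.tsv"))
        fio.write_tsv(self.srnas, os.path.join(outdir, "truth_srnas.tsv"))
        fio.write_tsv(self.categories, os.path.join(outdir, "truth_categories.tsv"))


@dataclass
class SyntheticDataset:
    """One generated dataset: probe intensities, annotation and ground truth."""

    config: SimulationConfig
    probes: pd.DataFrame  # probe_id, array_id, intensity
    probe_map: pd.DataFrame  # probe_id, transcript_id, is_control
    annotation: pd.DataFrame  # transcript_id, class, partner_id, strand
    design: pd.DataFrame  # array_id, timepoint, replicate
    gene_sets: dict[str, dict]
    truth: TruthTable

    @property
    def marker_id(self) -> str:
        return "mRNA-0001"

    def intensity_matrix(self) -> pd.DataFrame:
        """Probe x array wide matrix of raw intensities."""
        return self.probes.pivot(index="probe_id", columns="array_id", values="intensity")

    def write(self, outdir: str | os.PathLike) -> None:
        fio.ensure_dir(outdir)
        fio.write_tsv(self.probes, os.path.join(outdir, "probes.tsv"))
        fio.write_tsv(self.probe_map, os.path.join(outdir, "probe_map.tsv"))
        fio.write_tsv(self.annotation, os.path.join(outdir, "annotation.tsv"))
        fio.write_tsv(self.design, os.path.join(outdir, "design.tsv"))
        fio.write_gmt(self.gene_sets, os.path.join(outdir, "gene_sets.gmt"))
        self.truth.write(outdir)


def _transcript_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}-{i + 1:04d}" for i in range(n)]


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one probe-level dataset with planted ground truth.

    See the module docstring for the planted structure.  The marker gene is
    always ``mRNA-0001`` and is forced to be a strong monotone-up responder
    (the *isiA* analog) so the sRNA marker screen has a fixed anchor.
    """
    rng = np.random.default_rng(config.seed)
    tps = np.asarray(config.timepoints, dtype=float)
    n_tp = len(tps)

    mrna_ids = _transcript_ids("mRNA", config.n_mrna)
    asrna_ids = _transcript_ids("asRNA", config.n_asrna)
    srna_ids = _transcript_ids("sRNA", config.n_srna)
    unexpr_ids = _transcript_ids("low", config.n_unexpressed)
    all_ids = mrna_ids + asrna_ids + srna_ids + unexpr_ids
    n_transcripts = len(all_ids)
    tclass = (
        ["mRNA"] * config.n_mrna
        + ["asRNA"] * config.n_asrna
        + ["sRNA"] * config.n_srna
        + ["mRNA"] * config.n_unexpressed
    )

    # --- archetypes for mRNAs and sRNAs -----------------------------------
    archetype = np.array(["flat"] * n_transcripts, dtype=object)

    srna_slice = slice(
        config.n_mrna + config.n_asrna, config.n_mrna + config.n_asrna + config.n_srna
    )
    # mRNA responders always include the marker gene (index 0), so the
    # responder count is exactly round(fraction * n_mrna)
    n_resp_mrna = max(1, int(round(config.fraction_responders * config.n_mrna)))
    others = rng.choice(
        np.arange(1, config.n_mrna), size=n_resp_mrna - 1, replace=False
    )
    mrna_resp = np.concatenate([[0], others]).astype(int)
    archetype[mrna_resp] = rng.choice(ARCHETYPES[1:], size=len(mrna_resp))

    n_resp_srna = int(round(config.fraction_responders * config.n_srna))
    srna_resp = srna_slice.start + rng.choice(
        config.n_srna, size=n_resp_srna, replace=False
    )
    archetype[srna_resp] = rng.choice(ARCHETYPES[1:], size=n_resp_srna)

    # marker gene: forced strong monotone-up responder (isiA analog)
    archetype[0] = "monotone-up"

    shapes = {a: archetype_shape(a, tps) for a in ARCHETYPES}
    true_fc = np.vstack([config.effect_size * shapes[a] for a in archetype])
    # marker gets 1.5x amplitude so it is unambiguously differentially expressed
    true_fc[0] = 1.5 * config.effect_size * shapes["monotone-up"]

    # --- asRNA coupling ----------------------------------------------------
    # asRNA partners are drawn first from responder mRNAs (planted pairs in
    # which both members respond), then from non-responders.
    resp_partners = [i for i in mrna_resp if i != 0]
    rng.shuffle(resp_partners)
    n_pairs_wanted = min(config.n_asrna, len(resp_partners))
    class_labels = rng.choice(PAIR_CLASSES, size=n_pairs_wanted, p=config.pair_class_mix)
    partner_idx = np.full(config.n_asrna, -1, dtype=int)
    pair_rows = []
    nonresp_pool = [
        i for i in range(config.n_mrna) if archetype[i] == "flat"
    ]
    rng.shuffle(nonresp_pool)
    for j in range(config.n_asrna):
        as_idx = config.n_mrna + j
        if j < n_pairs_wanted:
            s_idx = resp_partners[j]
            label = str(class_labels[j])
            latent = plant_pair(true_fc[s_idx], label, 0.0, rng)
            true_fc[as_idx] = latent
            archetype[as_idx] = f"pair-{label}"
            partner_idx[as_idx - config.n_mrna] = s_idx
            pair_rows.append((all_ids[as_idx], all_ids[s_idx], label))
        elif nonresp_pool:
            s_idx = nonresp_pool.pop()
            partner_idx[j] = s_idx

    # --- marker-tracking sRNAs ---------------------------------------------
    srna_truth_sign = np.zeros(config.n_srna, dtype=int)
    n_track = min(config.n_marker_srnas, config.n_srna)
    track = rng.choice(config.n_srna, size=n_track, replace=False)
    signs = np.where(rng.random(n_track) < 0.5, 1, -1)
    for k, sign in zip(track, signs):
        idx = srna_slice.start + k
        true_fc[idx] = sign * true_fc[0]
        archetype[idx] = "marker-tracking"
        srna_truth_sign[k] = sign

    # non-tracking responder sRNAs must not mimic the marker profile, or the
    # screen's false-positive bookkeeping is meaningless; monotone-up sRNAs
    # that were not planted as tracking are rerouted to transient-up
    for k in range(config.n_srna):
        idx = srna_slice.start + k
        if srna_truth_sign[k] == 0 and archetype[idx] in ("monotone-up", "monotone-down"):
            new_arch = "transient-up" if archetype[idx] == "monotone-up" else "transient-down"
            archetype[idx] = new_arch
            true_fc[idx] = config.effect_size * shapes[new_arch]

    # --- baselines and expressed flags -------------------------------------
    lo, hi = config.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=n_transcripts)
    # strongly induced transcripts rise from moderate baselines: a transcript
    # already at the top of the intensity distribution cannot gain rank, so
    # quantile normalization would clip its induction (as on a real array)
    moderate_hi = lo + 0.4 * (hi - lo)
    baseline[0] = rng.uniform(lo, moderate_hi)
    for k, sign in zip(track, signs):
        if sign > 0:
            baseline[srna_slice.start + k] = rng.uniform(lo, moderate_hi)
    floor_log2 = np.log2(config.detection_floor)
    n_expr = n_transcripts - config.n_unexpressed
    baseline[n_expr:] = rng.uniform(floor_log2 - 4.0, floor_log2 - 0.5, size=config.n_unexpressed)
    true_fc[n_expr:] = 0.0
    archetype[n_expr:] = "flat"
    expressed = np.ones(n_transcripts, dtype=bool)
    expressed[n_expr:] = False

    # --- gene-set categories ------------------------------------------------
    categories: dict[str, dict] = {}
    cat_rows = []
    up_resp = [i for i in range(config.n_mrna) if archetype[i] in ("monotone-up", "transient-up")]
    for c in range(config.n_categories):
        set_id = f"CAT{c + 1:02d}"
        enriched = c < config.n_enriched_categories
        if enriched and len(up_resp) >= 2:
            k_resp = min(len(up_resp), max(2, int(0.8 * config.category_size)))
            members_idx = list(rng.choice(up_resp, size=k_resp, replace=False))
            pool = np.setdiff1d(np.arange(config.n_mrna), members_idx)
            n_fill = min(config.category_size - k_resp, len(pool))
            if n_fill > 0:
                members_idx.extend(
                    int(i) for i in rng.choice(pool, size=n_fill, replace=False)
                )
        else:
            members_idx = list(
                rng.choice(config.n_mrna, size=min(config.category_size, config.n_mrna), replace=False)
            )
        categories[set_id] = {
            "description": "planted-enriched" if enriched else "background",
            "genes": [mrna_ids[i] for i in members_idx],
        }
        cat_rows.append((set_id, enriched))

    # --- probe-level intensities -------------------------------------------
    arrays = []
    for t_i, t in enumerate(tps):
        for r in range(config.arrays_per_timepoint):
            arrays.append((f"T{t_i}R{r + 1}", t, r + 1))
    design = pd.DataFrame(arrays, columns=["array_id", "timepoint", "replicate"])
    n_arrays = len(design)
    array_effect = (
        rng.normal(0.0, config.array_effect_sd, size=n_arrays)
        if config.array_effect_sd > 0
        else np.zeros(n_arrays)
    )

    ppt = config.probes_per_transcript
    probe_ids = [
        f"{tid}|p{p + 1}" for tid in all_ids for p in range(ppt)
    ]
    control_probe_ids = [f"CTRL|{i + 1:04d}" for i in range(config.n_control)]

    tp_index = design["timepoint"].map({t: i for i, t in enumerate(tps)}).to_numpy()
    # signal probes: log2 = baseline + true_fc[timepoint] + array effect + noise
    base_mat = np.repeat(baseline, ppt)[:, None]
    fc_mat = np.repeat(true_fc, ppt, axis=0)[:, tp_index]
    noise = rng.normal(0.0, config.noise_sd, size=(len(probe_ids), n_arrays))
    log2_signal = base_mat + fc_mat + array_effect[None, :] + noise
    # control spots: low-intensity null, independent of time; per-spot base
    # level plus measurement noise, so noise_sd = 0 gives identical arrays
    ctrl_base = rng.normal(
        config.control_log2_mean, config.control_log2_sd, size=config.n_control
    )
    log2_ctrl = ctrl_base[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_control, n_arrays)
    )

    all_probe_ids = probe_ids + control_probe_ids
    intensity = np.vstack([2.0 ** log2_signal, 2.0 ** log2_ctrl])
    probes = pd.DataFrame(
        {
            "probe_id": np.repeat(all_probe_ids, n_arrays),
            "array_id": np.tile(design["array_id"].to_numpy(), len(all_probe_ids)),
            "intensity": intensity.ravel(),
        }
    )

    probe_map = pd.DataFrame(
        {
            "probe_id": all_probe_ids,
            "transcript_id": [pid.split("|")[0] for pid in probe_ids]
            + [""] * config.n_control,
            "is_control": [False] * len(probe_ids) + [True] * config.n_control,
        }
    )

    partner_full = [""] * n_transcripts
    for j in range(config.n_asrna):
        if partner_idx[j] >= 0:
            partner_full[config.n_mrna + j] = all_ids[partner_idx[j]]
    annotation = pd.DataFrame(
        {
            "transcript_id": all_ids,
            "class": tclass,
            "partner_id": partner_full,
            "strand": ["+"] * n_transcripts,
        }
    )

    truth_tx = pd.DataFrame(
        {
            "transcript_id": all_ids,
            "class": tclass,
            "archetype": archetype,
            "expressed": expressed,
            "baseline_log2": baseline,
        }
    )
    for i, t in enumerate(tps):
        truth_tx[f"true_fc_{t:g}h"] = true_fc[:, i]

    truth = TruthTable(
        transcripts=truth_tx,
        pairs=pd.DataFrame(pair_rows, columns=["antisense_id", "sense_id", "pair_class"]),
        srnas=pd.DataFrame({"srna_id": srna_ids, "marker_sign": srna_truth_sign}),
        categories=pd.DataFrame(cat_rows, columns=["set_id", "enriched"]),
    )

    return SyntheticDataset(
        config=config,
        probes=probes,
        probe_map=probe_map,
        annotation=annotation,
        design=design,
        gene_sets=categories,
        truth=truth,
    )


def config_from_dict(payload: dict) -> SimulationConfig:
    """Build a SimulationConfig from a parsed YAML/JSON mapping."""
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(payload) - fields
    if unknown:
        raise ConfigError(f"unknown simulation fields: {sorted(unknown)}")
    clean = dict(payload)
    for key in ("timepoints", "pair_class_mix", "baseline_log2_range"):
        if key in clean:
            clean[key] = tuple(clean[key])
    return SimulationConfig(**clean)
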