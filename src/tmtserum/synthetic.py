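"""Synthetic TMT study generator (and ELISA plates) with the statistical
structure the analysis assumes.

The generator emulates the serum study layout: 30 patients (20 with no
recovery, 10 with strong recovery) spread over three TMT 11-plexes, each
plex holding ten experimental channels plus one pooled-reference channel.
Reporter intensities follow an additive model on the log2 scale —

    latent = protein baseline + group effect + plex offset + centre offset
             + biological noise + peptide ionisation offset + measurement noise

— and the raw intensity is 2^latent.  Missingness combines an
intensity-dependent (MNAR) logistic mechanism with a completely-at-random
floor.  Ground truth (true effects, batch offsets, affected set) is
returned alongside so parameter-recovery tests can score the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CHANNELS, PSM_COLUMNS, validate_metadata
from .elisa import five_pl

#: Biological-noise prior: per-protein variances are drawn as a scaled
#: inverse chi-square with these hyper-parameters.  PRIOR_SCALE was
#: calibrated once so that the *final* protein matrix (after roll-ups,
#: normalisation and batch correction) has a median per-protein sample SD
#: close to the 0.4375 the analysis is tuned to.
PRIOR_DF = 6.0
PRIOR_SCALE_FACTOR = 0.94  # s0 = factor x protein_sd_target


@dataclass
class StudyDesign:
    """Parameters of a synthetic TMT recovery study.

    Defaults reproduce the cohort layout: 20 NR / 10 SR patients over three
    11-channel plexes, a log2 effect of 0.68 on the affected third of
    proteins (so the null fraction matches pi0 = 0.66) and a median
    protein-level SD near 0.4375.
    """

    n_nr: int = 20
    n_sr: int = 10
    n_plexes: int = 3
    channels_per_plex: int = 11
    n_proteins: int = 300
    peptides_per_protein: tuple[int, int] = (1, 20)
    psms_per_peptide: tuple[int, int] = (1, 5)
    frac_affected: float = 0.34
    effect_size_log2: float = 0.68
    protein_sd_target: float = 0.4375
    plex_effect_sd: float = 0.20
    centre_effect_sd: float = 0.10
    missing_mcar: float = 0.02
    missing_mnar_slope: float = 1.2
    missing_mnar_threshold: float = 11.0
    frac_shared_peptides: float = 0.05
    frac_no_accession: float = 0.02
    frac_redundant: float = 0.03
    baseline_mean: float = 14.0
    baseline_sd: float = 1.5
    peptide_offset_sd: float = 0.8
    peptide_noise_sd: float = 0.12
    psm_noise_sd: float = 0.08
    ref_noise_sd: float = 0.03
    rng_seed: int = 0

    def __post_init__(self):
        if self.channels_per_plex != len(CHANNELS):
            raise ValueError("channels_per_plex must be 11 for TMT 11-plex")
        if self.n_nr + self.n_sr > self.n_plexes * (self.channels_per_plex - 1):
            raise ValueError(
                f"infeasible design: {self.n_nr + self.n_sr} samples do not fit "
                f"{self.n_plexes} plexes x {self.channels_per_plex - 1} channels"
            )
        for name in ("frac_affected", "missing_mcar", "frac_shared_peptides",
                     "frac_no_accession", "frac_redundant"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery scoring."""

    protein_effects: pd.Series        # signed true log2 effect, NR vs SR
    affected: pd.Index                # proteins with a non-zero effect
    protein_baseline: pd.Series
    protein_sd: pd.Series
    plex_offsets: pd.DataFrame        # protein x plex
    centre_offsets: pd.DataFrame      # protein x centre
    peptide_offsets: pd.Series        # peptide -> ionisation offset
    peptide_protein: pd.Series = field(default=None)  # peptide -> accession(s)

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({
            "true_logfc": self.protein_effects,
            "affected": self.protein_effects.index.isin(self.affected),
            "baseline": self.protein_baseline,
            "sd": self.protein_sd,
        })
        out.index.name = "protein"
        out.to_csv(path, sep="\t")


def _build_metadata(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_nr + design.n_sr
    groups = ["NR"] * design.n_nr + ["SR"] * design.n_sr
    sample_ids = [f"P{i + 1:02d}" for i in range(n)]
    plex_of = [f"plex{(i % design.n_plexes) + 1}" for i in range(n)]
    # centre alternates within group so batch is crossed with (not aliased to)
    # the biological contrast
    centre_of, counters = [], {"NR": 0, "SR": 0}
    for g in groups:
        centre_of.append("Murnau" if counters[g] % 2 == 0 else "Toledo")
        counters[g] += 1
    slot = {p: 0 for p in set(plex_of)}
    channel_of = []
    for p in plex_of:
        channel_of.append(CHANNELS[slot[p]])
        slot[p] += 1
    rows = []
    for i in range(n):
        rows.append({
            "sample_id": sample_ids[i], "plex": plex_of[i],
            "channel": channel_of[i], "role": "experimental",
            "group": groups[i], "centre": centre_of[i],
            "sex": "female" if rng.random() < 0.33 else "male",
            "age": int(rng.integers(18, 80)),
            "injury_level": "tetraplegia" if rng.random() < 0.3 else "paraplegia",
            "ais_grade": "A" if rng.random() < 0.8 else "B",
            "storage_days": float(np.round(rng.uniform(30, 1200), 1)),
        })
    for q in range(design.n_plexes):
        rows.append({
            "sample_id": f"ref_plex{q + 1}", "plex": f"plex{q + 1}",
            "channel": CHANNELS[-1], "role": "reference_pool",
            "group": "", "centre": "", "sex": "", "age": np.nan,
            "injury_level": "", "ais_grade": "", "storage_days": np.nan,
        })
    meta = pd.DataFrame(rows)
    validate_metadata(meta)
    return meta


def generate_study(design: StudyDesign) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (PSM table, sample metadata, ground truth) for one study.

    Deterministic given ``design.rng_seed``.  Reporter intensities are
    positive; the reference channel of each plex carries the across-sample
    mean signal plus pool noise; missingness rises as the latent intensity
    falls below ``missing_mnar_threshold`` on top of an MCAR floor.
    """
    rng = np.random.default_rng(design.rng_seed)
    meta = _build_metadata(design, rng)
    exp = meta[meta["role"] == "experimental"].reset_index(drop=True)
    n_samples = len(exp)
    plexes = [f"plex{q + 1}" for q in range(design.n_plexes)]
    centres = sorted(exp["centre"].unique())

    # --- protein layer -----------------------------------------------------
    prots = pd.Index([f"PROT{i + 1:04d}" for i in range(design.n_proteins)],
                     name="protein")
    baseline = rng.normal(design.baseline_mean, design.baseline_sd,
                          design.n_proteins)
    s0 = PRIOR_SCALE_FACTOR * design.protein_sd_target
    sd = np.sqrt(PRIOR_DF * s0 ** 2 / rng.chisquare(PRIOR_DF, design.n_proteins))
    n_aff = int(round(design.frac_affected * design.n_proteins))
    affected_idx = rng.choice(design.n_proteins, size=n_aff, replace=False)
    effects = np.zeros(design.n_proteins)
    signs = rng.choice([-1.0, 1.0], size=n_aff)
    effects[affected_idx] = signs * design.effect_size_log2
    plex_off = rng.normal(0.0, design.plex_effect_sd,
                          (design.n_proteins, design.n_plexes))
    centre_off = rng.normal(0.0, design.centre_effect_sd,
                            (design.n_proteins, len(centres)))

    group_sign = np.where(exp["group"] == "NR", 0.5, -0.5)  # logFC = NR - SR
    plex_idx = exp["plex"].map({p: i for i, p in enumerate(plexes)}).to_numpy()
    centre_idx = exp["centre"].map({c: i for i, c in enumerate(centres)}).to_numpy()

    eps = rng.normal(0.0, 1.0, (design.n_proteins, n_samples)) * sd[:, None]
    bio = baseline[:, None] + effects[:, None] * group_sign[None, :] \
        + centre_off[:, centre_idx] + eps
    X = bio + plex_off[:, plex_idx]
    # pooled reference: equal aliquots of every sample, mixed on the raw scale
    pool = np.log2(np.mean(2.0 ** bio, axis=1))
    ref = pool[:, None] + rng.normal(0.0, design.ref_noise_sd,
                                     (design.n_proteins, design.n_plexes))

    # --- peptide layer -----------------------------------------------------
    lo, hi = design.peptides_per_protein
    pep_counts = rng.integers(lo, hi + 1, design.n_proteins)
    pep_prot = np.repeat(np.arange(design.n_proteins), pep_counts)
    n_pep = pep_prot.size
    pep_ids = np.array([f"PEP{j + 1:06d}" for j in range(n_pep)])
    pep_offset = rng.normal(0.0, design.peptide_offset_sd, n_pep)
    shared = rng.random(n_pep) < design.frac_shared_peptides
    second_prot = rng.integers(0, design.n_proteins, n_pep)
    pep_groups = []
    for j in range(n_pep):
        accs = {prots[pep_prot[j]]}
        if shared[j] and second_prot[j] != pep_prot[j]:
            accs.add(prots[second_prot[j]])
        pep_groups.append(";".join(sorted(accs)))
    pep_noise = rng.normal(0.0, design.peptide_noise_sd, (n_pep, n_samples))
    pep_ref_noise = rng.normal(0.0, design.peptide_noise_sd,
                               (n_pep, design.n_plexes))

    # --- PSM layer, one block per plex ------------------------------------
    plo, phi = design.psms_per_peptide
    blocks = []
    for q, plex in enumerate(plexes):
        in_plex = exp.index[exp["plex"] == plex].to_numpy()
        chan_of_sample = {exp.loc[i, "channel"]: i for i in in_plex}
        n_psm = rng.integers(plo, phi + 1, n_pep)
        psm_pep = np.repeat(np.arange(n_pep), n_psm)
        m = psm_pep.size
        latent = np.empty((m, len(CHANNELS)))
        for c, ch in enumerate(CHANNELS):
            if ch == CHANNELS[-1]:  # reference pool channel
                base = ref[pep_prot[psm_pep], q] + pep_offset[psm_pep] \
                    + pep_ref_noise[psm_pep, q]
            elif ch in chan_of_sample:
                i = chan_of_sample[ch]
                base = X[pep_prot[psm_pep], i] + pep_offset[psm_pep] \
                    + pep_noise[psm_pep, i]
            else:
                latent[:, c] = np.nan
                continue
            latent[:, c] = base + rng.normal(0.0, design.psm_noise_sd, m)
        p_miss = design.missing_mcar + (1.0 - design.missing_mcar) / (
            1.0 + np.exp(-design.missing_mnar_slope
                         * (design.missing_mnar_threshold - latent)))
        drop = rng.random(latent.shape) < p_miss
        inten = 2.0 ** latent
        inten[drop] = np.nan

        block = pd.DataFrame(inten, columns=list(CHANNELS))
        block.insert(0, "plex", plex)
        block.insert(1, "peptide", pep_ids[psm_pep])
        block.insert(2, "protein_groups",
                     np.array(pep_groups, dtype=object)[psm_pep])
        block.insert(3, "interference",
                     np.round(100.0 * rng.beta(1.2, 3.5, m), 2))
        rank = np.where(rng.random(m) < design.frac_redundant, 2, 1)
        block.insert(4, "rank", rank)
        no_acc = rng.random(m) < design.frac_no_accession
        block.loc[no_acc, "protein_groups"] = ""
        blocks.append(block)

    psm = pd.concat(blocks, ignore_index=True)[list(PSM_COLUMNS)]
    truth = GroundTruth(
        protein_effects=pd.Series(effects, index=prots, name="true_logfc"),
        affected=prots[np.sort(affected_idx)],
        protein_baseline=pd.Series(baseline, index=prots),
        protein_sd=pd.Series(sd, index=prots),
        plex_offsets=pd.DataFrame(plex_off, index=prots, columns=plexes),
        centre_offsets=pd.DataFrame(centre_off, index=prots, columns=centres),
        peptide_offsets=pd.Series(pep_offset, index=pep_ids),
        peptide_protein=pd.Series(pep_groups, index=pep_ids),
    )
    return psm, meta, truth


def generate_annotations(truth: GroundTruth, n_terms: int = 40,
                         enriched_terms: int = 5,
                         term_size: tuple[int, int] = (5, 30),
                         affected_weight: float = 0.75,
                         rng_seed: int = 0) -> dict:
    """Random annotation terms, some preferentially covering affected proteins.

    Returns a GMT-style mapping term -> (description, member set).  The first
    ``enriched_terms`` terms draw ``affected_weight`` of their members from
    the truly affected proteins; the rest draw uniformly.
    """
    if enriched_terms > n_terms:
        raise ValueError("enriched_terms cannot exceed n_terms")
    rng = np.random.default_rng(rng_seed)
    proteins = np.array(truth.protein_effects.index)
    affected = np.array([p for p in proteins if p in set(truth.affected)])
    others = np.array([p for p in proteins if p not in set(truth.affected)])
    terms = {}
    for t in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        size = min(size, len(proteins))
        if t < enriched_terms and len(affected):
            n_aff = min(int(round(affected_weight * size)), len(affected))
            members = set(rng.choice(affected, n_aff, replace=False))
            rest = min(size - n_aff, len(others))
            if rest > 0:
                members |= set(rng.choice(others, rest, replace=False))
            desc = "synthetic enriched term"
        else:
            members = set(rng.choice(proteins, size, replace=False))
            desc = "synthetic background term"
        if not members:
            members = {proteins[int(rng.integers(len(proteins)))]}
        terms[f"TERM{t + 1:03d}"] = (desc, frozenset(members))
    return terms


def generate_elisa_plate(curve_params: tuple[float, float, float, float, float],
                         n_standards: int = 7, n_blanks: int = 3,
                         sample_concs: dict | None = None,
                         dilutions: dict | None = None,
                         cv: float = 0.05,
                         standard_top: float = 1000.0,
                         standard_step: float = 3.0,
                         rng_seed: int = 0) -> pd.DataFrame:
    """Simulate one ELISA plate read at 450 nm.

    ``curve_params`` are the true 5PL parameters (a, d, c, b, g).  Standards
    follow a strictly decreasing serial dilution from ``standard_top`` by
    ``standard_step`` and are plated in duplicate, as is every sample; OD
    noise is multiplicative with coefficient of variation ``cv``; blanks are
    drawn around the curve's zero-concentration (lower) asymptote.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if standard_step <= 1:
        raise ValueError("standard_step must be > 1 (strictly decreasing series)")
    rng = np.random.default_rng(rng_seed)
    sample_concs = sample_concs or {}
    dilutions = dilutions or {}

    def noisy(od: float) -> float:
        return float(od * max(1.0 + cv * rng.standard_normal(), 1e-6))

    rows = []
    concs = standard_top / standard_step ** np.arange(n_standards)
    for s, conc in enumerate(concs):
        for rep in (1, 2):
            rows.append({"well": f"STD{s + 1}", "role": "standard",
                         "analyte": "analyte", "nominal_conc": float(conc),
                         "od": noisy(five_pl(conc, *curve_params)),
                         "replicate": rep, "dilution": 1.0, "group": ""})
    a = curve_params[0]
    for b in range(n_blanks):
        rows.append({"well": f"BLANK{b + 1}", "role": "blank",
                     "analyte": "analyte", "nominal_conc": 0.0,
                     "od": noisy(a), "replicate": b + 1,
                     "dilution": 1.0, "group": ""})
    for sid, payload in sample_concs.items():
        conc, group = payload if isinstance(payload, tuple) else (payload, "")
        dil = float(dilutions.get(sid, 1.0))
        true_od = five_pl(conc / dil, *curve_params)
        for rep in (1, 2):
            rows.append({"well": sid, "role": "sample", "analyte": "analyte",
                         "nominal_conc": np.nan, "od": noisy(true_od),
                         "replicate": rep, "dilution": dil, "group": group})
    return pd.DataFrame(rows)
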