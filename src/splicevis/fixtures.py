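"""Synthetic TCGA-style datasets with a known ground-truth manifest.

The generator emulates the level-3 inputs the pipeline consumes — a GTF of
gene models, exon/junction/isoform/gene quantification TSVs and a raw
clinical table — so every module is testable without any download.  The
spliced structure is the classic cassette-exon pattern: within a gene, all
transcripts share flanking exons and differ by one skipped internal exon, and
the inclusion isoform's share of gene output differs between a tumor-like and
a normal-like group (emulating an exon skipped in normal tissue and included
in tumor tissue).  Survival times are exponential with an
expression-dependent hazard so cutoff-grouped Kaplan–Meier curves separate
when the configured effect is non-zero.

Everything is driven by one seeded RNG and fixed number formatting, so the
same seed and config give byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CHROM = "chr1"
STRAND = "+"
EXON_LEN = 120
INTRON_LEN = 380
GENE_SPACING = 100_000
GENE_START0 = 10_000


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic cohort.

    ``inclusion`` gives the cassette-isoform share of gene output per group;
    the defaults describe a strong tumor/normal splicing switch (0.9 vs 0.1)
    in a 200-sample cohort with moderate multiplicative noise.
    """

    seed: int
    n_genes: int = 1
    transcripts_per_gene: int = 2
    exons_per_transcript: int = 6
    cassette_index: int = 3  # 0-based: the fourth exon is the switching one
    n_samples: int = 200
    group_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "Solid Tissue Normal": 0.25,
            "Primary Solid Tumor": 0.75,
        }
    )
    inclusion: dict[str, float] = field(
        default_factory=lambda: {
            "Solid Tissue Normal": 0.1,
            "Primary Solid Tumor": 0.9,
        }
    )
    noise_sigma: float = 0.2  # log-normal measurement noise on abundances
    gene_abundance_mean: float = 1000.0
    gene_abundance_sigma: float = 0.5
    survival_baseline_hazard: float = 1.0 / 1500.0  # events per day
    survival_effect: float = 1.0  # log-hazard per SD of log isoform expression
    followup_max_days: float = 2000.0

    def __post_init__(self) -> None:
        if abs(sum(self.group_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")
        if set(self.inclusion) != set(self.group_fractions):
            raise ValueError("inclusion must give one level per group")
        if not (0 < self.cassette_index < self.exons_per_transcript - 1):
            raise ValueError("cassette exon must be internal")
        if self.transcripts_per_gene < 2:
            raise ValueError("need >= 2 transcripts for a cassette pattern")
        if self.exons_per_transcript < 3:
            raise ValueError("need >= 3 exons for an internal cassette")

    @classmethod
    def from_json(cls, path) -> "FixtureConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


# ---------------------------------------------------------------------------
# gene models


def _gene_exon_coords(gene_idx: int, n_exons: int) -> list[tuple[int, int]]:
    """0-based half-open exon coordinates on the integer grid."""
    start = GENE_START0 + gene_idx * GENE_SPACING
    return [
        (start + k * (EXON_LEN + INTRON_LEN), start + k * (EXON_LEN + INTRON_LEN) + EXON_LEN)
        for k in range(n_exons)
    ]


def _skipped_exon(config: FixtureConfig, tx_rank: int) -> int | None:
    """Which exon transcript ``tx_rank`` skips (None for the full transcript)."""
    if tx_rank == 0:
        return None
    internal = list(range(1, config.exons_per_transcript - 1))
    return internal[(internal.index(config.cassette_index) + tx_rank - 1) % len(internal)]


def make_gene_models(config: FixtureConfig, outdir) -> dict:
    """Write the GTF and return the gene-model section of the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gtf_path = outdir / "models.gtf"
    genes = []
    with open(gtf_path, "w") as fh:
        for g in range(config.n_genes):
            gene_id = str(1001 + g)
            symbol = f"GENE{g + 1}"
            alias = f"SYN{g + 1}"
            coords = _gene_exon_coords(g, config.exons_per_transcript)
            tx_entries = []
            for k in range(config.transcripts_per_gene):
                tid = f"T{gene_id}.{k + 1}"
                skipped = _skipped_exon(config, k)
                exon_idx = [
                    i for i in range(config.exons_per_transcript) if i != skipped
                ]
                for i in exon_idx:
                    s0, e0 = coords[i]
                    fh.write(
                        "\t".join(
                            [
                                CHROM,
                                "splicevis-sim",
                                "exon",
                                str(s0 + 1),
                                str(e0),
                                ".",
                                STRAND,
                                ".",
                                f'gene_id "{gene_id}"; transcript_id "{tid}"; '
                                f'gene_name "{symbol}"; gene_alias "{alias}";',
                            ]
                        )
                        + "\n"
                    )
                tx_entries.append(
                    {
                        "transcript_id": tid,
                        "n_exons": len(exon_idx),
                        "skipped_exon_index": skipped,
                    }
                )
            genes.append(
                {
                    "gene_id": gene_id,
                    "symbol": symbol,
                    "aliases": [alias],
                    "chrom": CHROM,
                    "exon_coords_0based": coords,
                    "cassette_exon_index": config.cassette_index,
                    "transcripts": tx_entries,
                }
            )
    return {"gtf": str(gtf_path), "genes": genes}


# ---------------------------------------------------------------------------
# quantifications


def _group_assignment(config: FixtureConfig) -> list[str]:
    """Deterministic block assignment honoring the configured fractions."""
    labels = list(config.group_fractions)
    counts = [int(math.floor(config.group_fractions[g] * config.n_samples)) for g in labels]
    while sum(counts) < config.n_samples:
        counts[counts.index(min(counts))] += 1
    assignment = []
    for lab, c in zip(labels, counts):
        assignment.extend([lab] * c)
    return assignment[: config.n_samples]


def _exon_feature_id(coord: tuple[int, int]) -> str:
    return f"{CHROM}:{coord[0] + 1}-{coord[1]}:{STRAND}"


def _junction_feature_id(up: tuple[int, int], down: tuple[int, int]) -> str:
    donor = up[1]  # 1-based last base of the upstream exon
    acceptor = down[0] + 1  # 1-based first base of the downstream exon
    return f"{CHROM}:{donor}:{STRAND},{CHROM}:{acceptor}:{STRAND}"


def _write_matrix(path, feature_ids, sample_ids, values) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(sample_ids) + "\n")
        for fid, row in zip(feature_ids, values):
            fh.write(fid + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")


def make_quantifications(config: FixtureConfig, models: dict, outdir, rng) -> dict:
    """Write exon/junction/isoform/gene TSVs; return the manifest section.

    Per sample: a log-normal gene abundance is split across isoforms by the
    group's inclusion level (the cassette isoform gets ``inclusion``, the
    rest share the remainder equally); exon values are sums of the abundances
    of the isoforms containing the exon, junction values sums over isoforms
    in which the flanking exons are adjacent, each times multiplicative
    log-normal noise.
    """
    outdir = Path(outdir)
    sample_ids = [f"S{j + 1:04d}" for j in range(config.n_samples)]
    groups = _group_assignment(config)

    exon_fids: list[str] = []
    junc_fids: list[str] = []
    iso_ids: list[str] = []
    gene_ids: list[str] = []
    exon_rows: list[np.ndarray] = []
    junc_rows: list[np.ndarray] = []
    iso_rows: list[np.ndarray] = []
    gene_rows: list[np.ndarray] = []
    truth: dict = {"genes": {}}

    sigma = config.noise_sigma

    def noise(size):
        if sigma == 0:
            return np.ones(size)
        return np.exp(rng.normal(0.0, sigma, size=size))

    for gene in models["genes"]:
        coords = [tuple(c) for c in gene["exon_coords_0based"]]
        txs = gene["transcripts"]
        n_tx = len(txs)
        # per-sample gene abundance and isoform split
        g_abund = np.exp(
            rng.normal(
                math.log(config.gene_abundance_mean),
                config.gene_abundance_sigma,
                size=config.n_samples,
            )
        )
        incl = np.array([config.inclusion[g] for g in groups])
        iso_abund = np.zeros((n_tx, config.n_samples))
        iso_abund[0, :] = g_abund * incl
        if n_tx > 1:
            for k in range(1, n_tx):
                iso_abund[k, :] = g_abund * (1.0 - incl) / (n_tx - 1)

        tx_exons = [
            [i for i in range(config.exons_per_transcript) if i != t["skipped_exon_index"]]
            for t in txs
        ]
        # exon rows: all exons of the gene (union = full exon list)
        for i, coord in enumerate(coords):
            containing = [k for k in range(n_tx) if i in tx_exons[k]]
            base = iso_abund[containing, :].sum(axis=0)
            exon_fids.append(_exon_feature_id(coord))
            exon_rows.append(base * noise(config.n_samples))
        # junction rows: adjacent exon pairs across transcripts
        pair_to_txs: dict[tuple[int, int], list[int]] = {}
        for k, idxs in enumerate(tx_exons):
            for a, b in zip(idxs, idxs[1:]):
                pair_to_txs.setdefault((a, b), []).append(k)
        for (a, b) in sorted(pair_to_txs):
            base = iso_abund[pair_to_txs[(a, b)], :].sum(axis=0)
            junc_fids.append(_junction_feature_id(coords[a], coords[b]))
            junc_rows.append(base * noise(config.n_samples))
        # isoform and gene rows
        for k, t in enumerate(txs):
            iso_ids.append(t["transcript_id"])
            iso_rows.append(iso_abund[k, :] * noise(config.n_samples))
        gene_ids.append(gene["gene_id"])
        gene_rows.append(g_abund * noise(config.n_samples))

        truth["genes"][gene["gene_id"]] = {
            "cassette_exon_feature_id": _exon_feature_id(
                coords[gene["cassette_exon_index"]]
            ),
            "inclusion_isoform_id": txs[0]["transcript_id"],
            "gene_abundance_mean_config": config.gene_abundance_mean,
        }

    paths = {
        "exon": str(outdir / "exon.tsv"),
        "junction": str(outdir / "junction.tsv"),
        "isoform": str(outdir / "isoform.tsv"),
        "gene": str(outdir / "gene.tsv"),
    }
    _write_matrix(paths["exon"], exon_fids, sample_ids, exon_rows)
    _write_matrix(paths["junction"], junc_fids, sample_ids, junc_rows)
    _write_matrix(paths["isoform"], iso_ids, sample_ids, iso_rows)
    _write_matrix(paths["gene"], gene_ids, sample_ids, gene_rows)

    return {
        "paths": paths,
        "sample_ids": sample_ids,
        "group_of_sample": dict(zip(sample_ids, groups)),
        "group_sizes": {g: groups.count(g) for g in config.group_fractions},
        "inclusion": dict(config.inclusion),
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# clinical


_STAGE_TRUTH = ["I", "II", "III", "IV", "X", "UNDEFINED"]
_STAGE_PROBS = [0.25, 0.30, 0.22, 0.12, 0.05, 0.06]
_PACK_TRUTH = ["less than 10", "less than 100", "greater than 100", "UNDEFINED"]
_PACK_PROBS = [0.30, 0.40, 0.10, 0.20]
_RISK_TRUTH = ["Alcohol consumption", "hepatitis b", "hepatitis c", "others", "UNDEFINED"]
_RISK_PROBS = [0.30, 0.20, 0.15, 0.20, 0.15]
_ALC_TRUTH = ["0", ">0", "UNDEFINED"]
_ALC_PROBS = [0.40, 0.40, 0.20]
_PREG_TRUTH = ["1", "2", "3", "4", "5", ">5", "UNDEFINED"]
_PREG_PROBS = [0.15, 0.20, 0.15, 0.10, 0.05, 0.10, 0.25]
_RISK_OTHERS_RAW = ["Alpha-1 antitrypsin deficiency", "hemochromatosis", "other"]


def make_clinical(config: FixtureConfig, quant_manifest: dict, outdir, rng) -> dict:
    """Write the raw clinical TSV; return expected harmonized counts.

    Category truths are sampled first and then rendered into raw TCGA-style
    strings (substaged stage labels, numeric pack-years, ...), so the
    expected counts in the manifest are ground truth, not the output of the
    harmonizer.  Survival is exponential with log-hazard proportional to the
    standardized log expression of the inclusion isoform.
    """
    outdir = Path(outdir)
    sample_ids = quant_manifest["sample_ids"]
    n = len(sample_ids)

    # hazard driven by the first gene's inclusion isoform
    gene0 = sorted(quant_manifest["truth"]["genes"])[0]
    iso_id = quant_manifest["truth"]["genes"][gene0]["inclusion_isoform_id"]
    iso_path = quant_manifest["paths"]["isoform"]
    iso_expr = _read_row(iso_path, iso_id)
    logx = np.log1p(iso_expr)
    z = (logx - logx.mean()) / (logx.std() or 1.0)
    rate = config.survival_baseline_hazard * np.exp(config.survival_effect * z)

    t_death = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, config.followup_max_days, size=n)

    stage_t = rng.choice(len(_STAGE_TRUTH), size=n, p=_STAGE_PROBS)
    pack_t = rng.choice(len(_PACK_TRUTH), size=n, p=_PACK_PROBS)
    risk_t = rng.choice(len(_RISK_TRUTH), size=n, p=_RISK_PROBS)
    alc_t = rng.choice(len(_ALC_TRUTH), size=n, p=_ALC_PROBS)
    preg_t = rng.choice(len(_PREG_TRUTH), size=n, p=_PREG_PROBS)

    expected = {
        "sample_type": dict(quant_manifest["group_sizes"]),
        "stage": _count(_STAGE_TRUTH, stage_t),
        "pack_years": _count(_PACK_TRUTH, pack_t),
        "risk_factor": _count(_RISK_TRUTH, risk_t),
        "alcohol_per_day": _count(_ALC_TRUTH, alc_t),
        "pregnancies": _count(_PREG_TRUTH, preg_t),
    }

    n_events = 0
    path = outdir / "clinical.tsv"
    header = [
        "sample_id",
        "sample_type",
        "day_to_death",
        "days_to_last_follow-up",
        "pathology_stage",
        "number_pack_years_smoked",
        "risk_factor",
        "alcohol_per_day",
        "number_of_pregnancies",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for j, sid in enumerate(sample_ids):
            died = t_death[j] <= t_censor[j]
            if died:
                n_events += 1
                dtd = str(max(1, int(round(t_death[j]))))
                dlf = ""
            else:
                dtd = ""
                dlf = str(max(1, int(round(t_censor[j]))))

            st = _STAGE_TRUTH[stage_t[j]]
            if st == "UNDEFINED":
                stage_raw = "Indeterminate" if rng.random() < 0.5 else ""
            elif st == "X":
                stage_raw = "Stage X"
            else:
                sub = ["", "A", "B"][rng.choice(3)]
                stage_raw = f"Stage {st}{sub}"

            pk = _PACK_TRUTH[pack_t[j]]
            if pk == "UNDEFINED":
                pack_raw = ""
            elif pk == "less than 10":
                pack_raw = str(int(rng.integers(0, 10)))
            elif pk == "less than 100":
                pack_raw = str(int(rng.integers(10, 100)))
            else:
                pack_raw = str(int(rng.integers(100, 200)))

            rk = _RISK_TRUTH[risk_t[j]]
            if rk == "UNDEFINED":
                risk_raw = "Indeterminate" if rng.random() < 0.5 else ""
            elif rk == "others":
                risk_raw = _RISK_OTHERS_RAW[rng.choice(3)]
            else:
                risk_raw = rk

            al = _ALC_TRUTH[alc_t[j]]
            if al == "UNDEFINED":
                alc_raw = ""
            elif al == "0":
                alc_raw = "0"
            else:
                alc_raw = f"{rng.uniform(0.5, 5.0):.1f}"

            pg = _PREG_TRUTH[preg_t[j]]
            if pg == "UNDEFINED":
                preg_raw = ""
            elif pg == ">5":
                preg_raw = str(int(rng.integers(6, 11)))
            else:
                preg_raw = pg

            fh.write(
                "\t".join(
                    [
                        sid,
                        quant_manifest["group_of_sample"][sid],
                        dtd,
                        dlf,
                        stage_raw,
                        pack_raw,
                        risk_raw,
                        alc_raw,
                        preg_raw,
                    ]
                )
                + "\n"
            )

    return {
        "path": str(path),
        "expected_category_counts": expected,
        "n_events": n_events,
        "event_fraction": n_events / n,
        "survival_effect": config.survival_effect,
        "survival_isoform_id": iso_id,
    }


def _count(vocab, idx) -> dict[str, int]:
    return {v: int((idx == i).sum()) for i, v in enumerate(vocab)}


def _read_row(tsv_path, row_id) -> np.ndarray:
    with open(tsv_path) as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == row_id:
                return np.array([float(v) for v in parts[1:]])
    raise KeyError(row_id)


# ---------------------------------------------------------------------------


def simulate(config: FixtureConfig, outdir) -> dict:
    """Run all generators; write and return the full manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    models = make_gene_models(config, outdir)
    quant = make_quantifications(config, models, outdir, rng)
    clinical = make_clinical(config, quant, outdir, rng)
    manifest = {
        "config": {
            "seed": config.seed,
            "n_genes": config.n_genes,
            "transcripts_per_gene": config.transcripts_per_gene,
            "exons_per_transcript": config.exons_per_transcript,
            "cassette_index": config.cassette_index,
            "n_samples": config.n_samples,
            "group_fractions": config.group_fractions,
            "inclusion": config.inclusion,
            "noise_sigma": config.noise_sigma,
            "survival_effect": config.survival_effect,
        },
        "models": models,
        "quantifications": quant,
        "clinical": clinical,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["manifest_path"] = str(manifest_path)
    return manifest
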