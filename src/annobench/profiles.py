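"""Functional-profile analyses: KO abundance aggregation, length
normalization, single-copy-marker copy-number estimation, Jensen-Shannon
profile distances, per-KO mappability statistics, pathway aggregation,
hypergeometric enrichment, and protocol comparison.

Copy numbers follow the standard marker normalization: a KO's
length-normalized count divided by the mean length-normalized count of a
panel of universal single-copy marker genes, so that in a perfectly
annotated, evenly covered dataset a two-copy KO scores exactly 2.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import hypergeom, wilcoxon
from statsmodels.stats.multitest import multipletests

from .evaluate import ReadClassification
from .protocols import WeightedAssignment
from .reference import KOCatalog, Origin, ValidationError

NORMALIZATION_MODES = ("aligned_gene", "ko_mean")


@dataclass
class FunctionalProfile:
    """Aggregated KO counts for one read set.

    ``counts`` are summed fractional read weights; ``norm_counts`` divide by
    an effective gene length in bp (either the subject gene each read aligned
    to, or the KO-wide mean member length).
    """

    counts: dict[str, float] = field(default_factory=dict)
    norm_counts: dict[str, float] = field(default_factory=dict)
    normalization_mode: str = "aligned_gene"
    copy_nums: dict[str, float] = field(default_factory=dict)
    marker_kos: list[str] = field(default_factory=list)

    @property
    def total_count(self) -> float:
        return sum(self.counts.values())


def aggregate_profile(
    assignments: Iterable[WeightedAssignment],
    catalog: KOCatalog,
    mode: str = "aligned_gene",
) -> FunctionalProfile:
    """Sum fractional KO counts over reads and length-normalize them.

    mode='aligned_gene': each hit's KO contribution is divided by the length
    of the gene it aligned to (weight-averaged reciprocal lengths for
    multi-hit reads) — approximating the unknown source-gene length by the
    subject's.  mode='ko_mean': totals are divided by the mean length of the
    KO's member genes.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    counts: dict[str, float] = {}
    norm: dict[str, float] = {}
    for a in assignments:
        if a.status != "annotated":
            continue
        if mode == "aligned_gene":
            if not a.considered:
                raise ValidationError(
                    f"read {a.read_id}: aligned_gene normalization needs considered hits"
                )
            for hit in a.considered:
                if not hit.ko_ids:
                    continue
                length = catalog.gene_to_length.get(hit.gene_id)
                if not length:
                    raise ValidationError(f"zero/unknown length for gene {hit.gene_id}")
                share = hit.weight / len(hit.ko_ids)
                for ko in hit.ko_ids:
                    counts[ko] = counts.get(ko, 0.0) + share
                    norm[ko] = norm.get(ko, 0.0) + share / length
        else:
            for ko, w in a.ko_weights.items():
                counts[ko] = counts.get(ko, 0.0) + w
    if mode == "ko_mean":
        for ko, c in counts.items():
            norm[ko] = c / catalog.mean_gene_length(ko)
    return FunctionalProfile(counts=counts, norm_counts=norm, normalization_mode=mode)


def copy_numbers(profile: FunctionalProfile, markers: Sequence[str]) -> dict[str, float]:
    """Estimate per-KO copy numbers against single-copy marker KOs.

    C_k = norm_count[k] / mean over markers of norm_count[m]; markers absent
    from the profile contribute 0 to the mean.  KOs absent from the profile
    get C = 0.
    """
    if not markers:
        raise ValidationError("marker list is empty")
    marker_mean = float(np.mean([profile.norm_counts.get(m, 0.0) for m in markers]))
    if marker_mean <= 0:
        raise ValidationError("no marker KO observed with positive normalized count")
    out = {ko: v / marker_mean for ko, v in profile.norm_counts.items()}
    profile.copy_nums = out
    profile.marker_kos = list(markers)
    return out


def _as_distribution(p: Mapping[str, float] | Sequence[float], keys: Sequence[str] | None):
    if isinstance(p, Mapping):
        vec = np.array([max(p.get(k, 0.0), 0.0) for k in keys], dtype=float)
    else:
        vec = np.asarray(p, dtype=float)
    total = vec.sum()
    if total <= 0:
        raise ValidationError("cannot normalize an all-zero profile to a distribution")
    return vec / total


def jsd_distance(
    p: Mapping[str, float] | Sequence[float],
    q: Mapping[str, float] | Sequence[float],
) -> float:
    """Jensen-Shannon distance (sqrt of the base-2 divergence), in [0, 1].

    Dict inputs are zero-filled over the union of keys and normalized to
    sum 1; 0·log 0 is treated as 0.  The result is a metric on
    distributions: symmetric, zero iff p = q, and obeying the triangle
    inequality.
    """
    if isinstance(p, Mapping) and isinstance(q, Mapping):
        keys = sorted(set(p) | set(q))
    else:
        keys = None
    pv = _as_distribution(p, keys)
    qv = _as_distribution(q, keys)
    if pv.shape != qv.shape:
        raise ValidationError("profiles have different dimensions")
    d = float(jensenshannon(pv, qv, base=2))
    # scipy can return tiny negative/NaN values for identical inputs
    if np.isnan(d):
        return 0.0
    return min(max(d, 0.0), 1.0)


@dataclass
class KOStats:
    """Per-KO mean recall across datasets with catalog-derived properties."""

    ko: str
    mean_recall: float
    ci_low: float
    ci_high: float
    n_datasets: int
    mean_gene_length: float
    sd_gene_length: float
    cv_gene_length: float
    n_genes: int
    n_genomes: int
    genes_per_genome_mean: float
    genes_per_genome_sd: float


def per_ko_recall(
    classifications_by_dataset: Mapping[str, Sequence[ReadClassification]],
    catalog: KOCatalog,
) -> pd.DataFrame:
    """Average recall per KO across datasets with 95% normal-approximation CIs.

    A read counts toward a KO if its source gene carries that KO (reads from
    multi-KO genes count toward each).  KOs never observed as a read origin
    are omitted.
    """
    if not classifications_by_dataset:
        raise ValidationError("need at least one dataset")
    per_dataset: dict[str, dict[str, float]] = {}
    for ds, classifications in classifications_by_dataset.items():
        num: dict[str, float] = {}
        den: dict[str, int] = {}
        for c in classifications:
            if c.skipped or c.origin is not Origin.KO_GENE:
                continue
            for ko in c.source_kos:
                den[ko] = den.get(ko, 0) + 1
                num[ko] = num.get(ko, 0.0) + c.correct_ko_weight
        per_dataset[ds] = {ko: num.get(ko, 0.0) / n for ko, n in den.items()}

    kos = sorted(set().union(*(set(d) for d in per_dataset.values())))
    rows = []
    for ko in kos:
        vals = [d[ko] for d in per_dataset.values() if ko in d]
        mean = float(np.mean(vals))
        if len(vals) > 1:
            se = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
        else:
            se = 0.0
        lengths = np.array([catalog.gene_to_length[g] for g in catalog.ko_to_genes[ko]], dtype=float)
        genomes = [catalog.gene_to_genome[g] for g in catalog.ko_to_genes[ko]]
        per_genome = pd.Series(genomes).value_counts().to_numpy(dtype=float)
        mean_len = float(lengths.mean())
        sd_len = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
        rows.append(
            KOStats(
                ko=ko,
                mean_recall=mean,
                ci_low=max(mean - 1.96 * se, 0.0),
                ci_high=min(mean + 1.96 * se, 1.0),
                n_datasets=len(vals),
                mean_gene_length=mean_len,
                sd_gene_length=sd_len,
                cv_gene_length=sd_len / mean_len if mean_len else float("nan"),
                n_genes=len(lengths),
                n_genomes=len(set(genomes)),
                genes_per_genome_mean=float(per_genome.mean()),
                genes_per_genome_sd=float(per_genome.std(ddof=1)) if len(per_genome) > 1 else 0.0,
            ).__dict__
        )
    return pd.DataFrame(rows).set_index("ko")


def bottom_recall_kos(stats: pd.DataFrame, fraction: float = 0.05) -> set[str]:
    """KOs in the bottom ``fraction`` of mean recall, boundary ties included."""
    if stats.empty:
        return set()
    n = max(1, int(np.ceil(len(stats) * fraction)))
    ordered = stats["mean_recall"].sort_values(kind="stable")
    threshold = ordered.iloc[n - 1]
    return set(stats.index[stats["mean_recall"] <= threshold])


def pathway_enrichment(
    low_set: set[str],
    universe: set[str],
    ko_to_pathways: Mapping[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of pathways in a KO subset.

    For each pathway with members in the universe, tests whether the overlap
    with ``low_set`` is larger than expected under sampling without
    replacement; Benjamini–Hochberg q-values flag significance at q < 0.05.
    """
    if not low_set <= universe:
        raise ValidationError("low_set must be a subset of the universe")
    pathways: dict[str, set[str]] = {}
    for ko in universe:
        for pw in ko_to_pathways.get(ko, ()):
            pathways.setdefault(pw, set()).add(ko)
    rows = []
    M, N = len(universe), len(low_set)
    for pw in sorted(pathways):
        members = pathways[pw]
        k = len(members & low_set)
        p = float(hypergeom.sf(k - 1, M, len(members), N))
        rows.append({"pathway": pw, "overlap": k, "size": len(members), "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["pathway", "overlap", "size", "p"])
    if not df.empty:
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < 0.05
    else:
        df["q"] = []
        df["significant"] = []
    return df


def pathway_profiles(
    profiles: Mapping[str, FunctionalProfile | Mapping[str, float]],
    ko_to_pathways: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per-sample pathway abundances (rows: samples, columns: pathways).

    Each KO's abundance is added to every pathway it belongs to; each
    sample's vector is normalized to sum 1.  All-zero samples are returned
    as zero rows (flagged by the caller's inspection of row sums).
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    all_pathways = sorted({pw for pws in ko_to_pathways.values() for pw in pws})
    rows = {}
    for sample, prof in profiles.items():
        abundances = prof.norm_counts if isinstance(prof, FunctionalProfile) else prof
        vec = dict.fromkeys(all_pathways, 0.0)
        for ko, a in abundances.items():
            for pw in ko_to_pathways.get(ko, ()):
                vec[pw] += a
        total = sum(vec.values())
        if total > 0:
            vec = {pw: v / total for pw, v in vec.items()}
        rows[sample] = vec
    return pd.DataFrame.from_dict(rows, orient="index")[all_pathways]


@dataclass
class ProtocolComparison:
    inter_protocol: pd.DataFrame  # sample, protocol_a, protocol_b, jsd
    inter_sample: pd.DataFrame  # protocol, sample_a, sample_b, jsd
    differential: pd.DataFrame  # protocol, pathway, n_nonzero, statistic, p, q


def compare_protocols(
    vectors_by_protocol: Mapping[str, pd.DataFrame],
    reference_protocol: str | None = None,
    min_samples: int = 10,
) -> ProtocolComparison:
    """Contrast the profile variation introduced by protocol choice with the
    natural variation between samples.

    Inputs are per-protocol (samples x pathways) abundance tables over
    identical sample sets.  Computes within-sample Jensen-Shannon distances
    across protocols, within-protocol distances across samples, and paired
    Wilcoxon signed-rank tests of each pathway between the reference
    protocol and every other (BH-corrected), restricted to pathways with
    nonzero paired differences in at least ``min_samples`` samples.
    """
    protocols = sorted(vectors_by_protocol)
    if len(protocols) < 2:
        raise ValidationError("need at least two protocols")
    sample_sets = {p: tuple(vectors_by_protocol[p].index) for p in protocols}
    samples = sample_sets[protocols[0]]
    if any(sample_sets[p] != samples for p in protocols):
        raise ValidationError("protocols cover different sample sets")
    if len(samples) < 2:
        raise ValidationError("need at least two samples")
    if reference_protocol is None:
        reference_protocol = protocols[0]
    if reference_protocol not in vectors_by_protocol:
        raise ValidationError(f"reference protocol {reference_protocol!r} missing")

    inter_protocol = []
    for s in samples:
        for i, pa in enumerate(protocols):
            for pb in protocols[i + 1 :]:
                d = jsd_distance(
                    vectors_by_protocol[pa].loc[s].to_dict(),
                    vectors_by_protocol[pb].loc[s].to_dict(),
                )
                inter_protocol.append(
                    {"sample": s, "protocol_a": pa, "protocol_b": pb, "jsd": d}
                )
    inter_sample = []
    for p in protocols:
        tab = vectors_by_protocol[p]
        for i, sa in enumerate(samples):
            for sb in samples[i + 1 :]:
                inter_sample.append(
                    {
                        "protocol": p,
                        "sample_a": sa,
                        "sample_b": sb,
                        "jsd": jsd_distance(tab.loc[sa].to_dict(), tab.loc[sb].to_dict()),
                    }
                )

    diff_rows = []
    ref = vectors_by_protocol[reference_protocol]
    for p in protocols:
        if p == reference_protocol:
            continue
        other = vectors_by_protocol[p]
        for pw in ref.columns:
            diffs = (other[pw] - ref[pw]).to_numpy(dtype=float)
            n_nonzero = int(np.count_nonzero(diffs))
            if n_nonzero < min_samples:
                continue
            stat, pval = wilcoxon(diffs[diffs != 0.0])
            diff_rows.append(
                {
                    "protocol": p,
                    "pathway": pw,
                    "n_nonzero": n_nonzero,
                    "statistic": float(stat),
                    "p": float(pval),
                }
            )
    diff = pd.DataFrame(diff_rows, columns=["protocol", "pathway", "n_nonzero", "statistic", "p"])
    if not diff.empty:
        diff["q"] = multipletests(diff["p"], method="fdr_bh")[1]
        diff["significant"] = diff["q"] < 0.05
    else:
        diff["q"] = []
        diff["significant"] = []
    return ProtocolComparison(
        inter_protocol=pd.DataFrame(inter_protocol),
        inter_sample=pd.DataFrame(inter_sample),
        differential=diff,
    )


def write_profile_table(profile: FunctionalProfile, path: str | Path) -> None:
    rows = [
        {
            "ko_id": ko,
            "count": profile.counts.get(ko, 0.0),
            "norm_count": profile.norm_counts.get(ko, 0.0),
            "copy_number": profile.copy_nums.get(ko, float("nan")),
        }
        for ko in sorted(profile.counts)
    ]
    pd.DataFrame(rows, columns=["ko_id", "count", "norm_count", "copy_number"]).to_csv(
        path, sep="\t", index=False
    )
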