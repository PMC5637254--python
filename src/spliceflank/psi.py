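"""Per-sample inclusion levels (psi), condition contrasts (delta-psi), and
the significance/abundance filters that call condition-dependent splicing.

psi for an event in a sample is the TPM of the inclusion isoforms divided by
the TPM of all isoforms participating in the event; 0/0 is missing (an
unexpressed event carries no inclusion information). delta-psi is the mean
of non-missing replicate psi in the test (mutant) condition minus the mean
in the control condition.

Significance of delta-psi uses a replicate-label permutation test on
|delta-psi| (exact enumeration of all group relabelings when feasible,
Monte-Carlo otherwise).  Exact permutation p-values are discrete with
minimum 2/C(n, n_c); for designs too small to ever reach the requested
alpha (e.g. 3 vs 3 gives minimum p = 0.1) `call_sas` falls back to Welch's
t-test on the replicate psi values so the abundance/significance filter is
not vacuous.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .events import SpliceEvent


class MissingTranscriptError(KeyError):
    pass


@dataclass
class PsiResult:
    event_id: str
    event_type: str
    psi_per_sample: dict[str, float | None]
    mean_psi_control: float | None
    mean_psi_mutant: float | None
    delta_psi: float | None
    p_value: float | None
    total_mean_tpm: float
    is_sas: bool


def _check_transcripts(event: SpliceEvent, quant: pd.DataFrame) -> None:
    missing = [t for t in sorted(event.transcripts) if t not in quant.index]
    if missing:
        raise MissingTranscriptError(
            f"event {event.event_id}: transcripts absent from quantification "
            f"table: {', '.join(missing)}"
        )


def compute_psi(event: SpliceEvent, quant: pd.DataFrame,
                sample: str) -> float | None:
    """Inclusion level of `event` in one sample; None when the event's
    isoforms are all unexpressed there."""
    _check_transcripts(event, quant)
    col = quant[sample]
    incl = float(col.loc[sorted(event.inclusion_transcripts)].sum())
    excl = float(col.loc[sorted(event.exclusion_transcripts)].sum())
    total = incl + excl
    if total == 0.0:
        return None
    return incl / total


def event_total_mean_tpm(event: SpliceEvent, quant: pd.DataFrame) -> float:
    """Sum over the event's isoforms of their mean TPM across all samples."""
    _check_transcripts(event, quant)
    return float(
        quant.loc[sorted(event.transcripts)].mean(axis=1).sum()
    )


def _condition_samples(condition_map: pd.DataFrame,
                       control: str, mutant: str) -> tuple[list[str], list[str]]:
    cm = condition_map.set_index("sample")["condition"]
    ctrl = [s for s in cm.index if cm[s] == control]
    mut = [s for s in cm.index if cm[s] == mutant]
    if not ctrl or not mut:
        raise ValueError(
            f"condition map must contain samples for both {control!r} and "
            f"{mutant!r}"
        )
    return ctrl, mut


def delta_psi(event: SpliceEvent, quant: pd.DataFrame,
              condition_map: pd.DataFrame, control: str = "control",
              mutant: str = "mutant") -> float | None:
    """Mean non-missing mutant psi minus mean non-missing control psi;
    None when either condition has no defined psi."""
    ctrl, mut = _condition_samples(condition_map, control, mutant)
    pc = [p for p in (compute_psi(event, quant, s) for s in ctrl)
          if p is not None]
    pm = [p for p in (compute_psi(event, quant, s) for s in mut)
          if p is not None]
    if not pc or not pm:
        return None
    return float(np.mean(pm) - np.mean(pc))


def permutation_test(psi_control: list[float], psi_mutant: list[float],
                     n_perm: int = 10_000, seed: int = 1) -> float | None:
    """Two-sided replicate-label permutation p-value for |delta-psi|.

    All C(n, n_control) distinct relabelings are enumerated when that count
    is <= n_perm (p = fraction of relabelings, identity included, whose
    |delta-psi| >= observed); otherwise n_perm Monte-Carlo relabelings are
    drawn and p = (1 + extreme) / (1 + n_perm).  Returns None (with a
    warning) when either group has fewer than two non-missing replicates.
    """
    pc = [p for p in psi_control if p is not None and not math.isnan(p)]
    pm = [p for p in psi_mutant if p is not None and not math.isnan(p)]
    if len(pc) < 2 or len(pm) < 2:
        warnings.warn(
            "permutation test skipped: fewer than 2 replicates in a group",
            stacklevel=2,
        )
        return None
    pooled = np.asarray(pc + pm, dtype=float)
    n, nc = len(pooled), len(pc)
    obs = abs(pooled[nc:].mean() - pooled[:nc].mean())
    tol = 1e-12
    n_exact = math.comb(n, nc)
    if n_exact <= n_perm:
        extreme = 0
        for idx in combinations(range(n), nc):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            d = abs(pooled[~mask].mean() - pooled[mask].mean())
            if d >= obs - tol:
                extreme += 1
        return extreme / n_exact
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(perm[nc:].mean() - perm[:nc].mean())
        if d >= obs - tol:
            extreme += 1
    return (1 + extreme) / (1 + n_perm)


def min_exact_permutation_p(n_control: int, n_mutant: int) -> float:
    """Smallest attainable exact-permutation p: the observed split and its
    mirror are always counted, so the floor is 2/C(n, n_control)."""
    return 2.0 / math.comb(n_control + n_mutant, n_control)


def welch_test(psi_control: list[float], psi_mutant: list[float]) -> float | None:
    pc = [p for p in psi_control if p is not None and not math.isnan(p)]
    pm = [p for p in psi_mutant if p is not None and not math.isnan(p)]
    if len(pc) < 2 or len(pm) < 2:
        return None
    if np.var(pc) == 0.0 and np.var(pm) == 0.0:
        return 1.0 if np.mean(pc) == np.mean(pm) else 0.0
    res = stats.ttest_ind(pm, pc, equal_var=False)
    return float(res.pvalue)


def call_sas(events: list[SpliceEvent], quant: pd.DataFrame,
             condition_map: pd.DataFrame, alpha: float = 0.05,
             min_tpm: float = 10.0, control: str = "control",
             mutant: str = "mutant", test: str = "auto",
             n_perm: int = 10_000, seed: int = 1) -> list[PsiResult]:
    """Compute psi/delta-psi for every event and flag those passing the
    splicing-change filter: p < alpha (strict) and total mean TPM >= min_tpm.

    test: "permutation", "welch", or "auto" (permutation when its discrete
    resolution can reach alpha for the design, Welch otherwise).
    """
    if test not in ("auto", "permutation", "welch"):
        raise ValueError(f"unknown test {test!r}")
    ctrl, mut = _condition_samples(condition_map, control, mutant)
    results = []
    for ev in events:
        psis = {s: compute_psi(ev, quant, s) for s in ctrl + mut}
        pc = [psis[s] for s in ctrl if psis[s] is not None]
        pm = [psis[s] for s in mut if psis[s] is not None]
        mean_c = float(np.mean(pc)) if pc else None
        mean_m = float(np.mean(pm)) if pm else None
        dpsi = (mean_m - mean_c) if (pc and pm) else None
        tpm = event_total_mean_tpm(ev, quant)
        chosen = test
        if test == "auto":
            if (len(pc) >= 2 and len(pm) >= 2
                    and min_exact_permutation_p(len(pc), len(pm)) < alpha):
                chosen = "permutation"
            else:
                chosen = "welch"
        if chosen == "permutation":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = permutation_test(pc, pm, n_perm=n_perm, seed=seed)
        else:
            p = welch_test(pc, pm)
        is_sas = (p is not None and p < alpha and tpm >= min_tpm)
        results.append(PsiResult(
            event_id=ev.event_id, event_type=ev.event_type,
            psi_per_sample=psis, mean_psi_control=mean_c,
            mean_psi_mutant=mean_m, delta_psi=dpsi, p_value=p,
            total_mean_tpm=tpm, is_sas=is_sas,
        ))
    return results


def results_to_frame(results: list[PsiResult]) -> pd.DataFrame:
    """Flatten PsiResults into the output table shape."""
    rows = []
    for r in results:
        row = {"event_id": r.event_id, "event_type": r.event_type}
        for s, v in r.psi_per_sample.items():
            row[f"psi_{s}"] = np.nan if v is None else v
        row.update({
            "mean_psi_control": np.nan if r.mean_psi_control is None
            else r.mean_psi_control,
            "mean_psi_mutant": np.nan if r.mean_psi_mutant is None
            else r.mean_psi_mutant,
            "delta_psi": np.nan if r.delta_psi is None else r.delta_psi,
            "p_value": np.nan if r.p_value is None else r.p_value,
            "total_mean_tpm": r.total_mean_tpm,
            "is_sas": r.is_sas,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def read_quant(path: str) -> pd.DataFrame:
    quant = pd.read_csv(path, sep="\t", index_col="transcript_id")
    if (quant.values < 0).any():
        raise ValueError(f"{path}: negative abundance values")
    return quant


def read_condition_map(path: str) -> pd.DataFrame:
    cm = pd.read_csv(path, sep="\t")
    if list(cm.columns) != ["sample", "condition"]:
        raise ValueError(f"{path}: expected columns 'sample', 'condition'")
    return cm
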