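"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take the slow, direct route: explicit sums of squares for
the split-plot ANOVA, a declarative interval search for non-wear labelling,
and a literal threshold lookup for intensity bands.
"""

import numpy as np


def splitplot_f_oracle(df):
    """F statistics of a balanced split-plot design by explicit SS sums.

    ``df`` is long-format with subject_id/group/timepoint/value and equal
    group sizes.  Returns (F_group, F_time, F_interaction).
    """
    groups = sorted(df["group"].unique())
    tps = sorted(df["timepoint"].unique())
    k = len(tps)
    grand = df["value"].mean()

    ss_group = 0.0
    ss_subj = 0.0
    for g in groups:
        sub = df[df["group"] == g]
        gmean = sub["value"].mean()
        n_g = sub["subject_id"].nunique()
        ss_group += n_g * k * (gmean - grand) ** 2
        for s in sub["subject_id"].unique():
            smean = sub[sub["subject_id"] == s]["value"].mean()
            ss_subj += k * (smean - gmean) ** 2

    n_total = df["subject_id"].nunique()
    ss_time = 0.0
    for t in tps:
        tmean = df[df["timepoint"] == t]["value"].mean()
        ss_time += n_total * (tmean - grand) ** 2

    ss_inter = 0.0
    for g in groups:
        sub = df[df["group"] == g]
        gmean = sub["value"].mean()
        n_g = sub["subject_id"].nunique()
        for t in tps:
            cell = sub[sub["timepoint"] == t]["value"].mean()
            tmean = df[df["timepoint"] == t]["value"].mean()
            ss_inter += n_g * (cell - gmean - tmean + grand) ** 2

    ss_total = ((df["value"] - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj - ss_time - ss_inter

    g_n = len(groups)
    df_group = g_n - 1
    df_subj = n_total - g_n
    df_time = k - 1
    df_inter = df_group * df_time
    df_err = df_subj * df_time

    f_group = (ss_group / df_group) / (ss_subj / df_subj)
    f_time = (ss_time / df_time) / (ss_err / df_err)
    f_inter = (ss_inter / df_inter) / (ss_err / df_err)
    return f_group, f_time, f_inter


def nonwear_oracle(vm, window=90, tol=2, flank=30):
    """Declarative non-wear labelling by interval search (O(n^2)-ish).

    A minute is non-wear iff it lies inside some interval of length >= window
    that starts and ends on zero minutes and whose every interior nonzero run
    is <= tol minutes long and flanked by >= flank zeros on both sides in the
    full stream.
    """
    vm = np.asarray(vm, dtype=float)
    n = vm.size
    nonwear = np.zeros(n, dtype=bool)

    # maximal nonzero runs with their flanking zero-run lengths
    runs = []
    i = 0
    while i < n:
        if vm[i] == 0:
            i += 1
            continue
        j = i
        while j < n and vm[j] != 0:
            j += 1
        left = 0
        p = i - 1
        while p >= 0 and vm[p] == 0:
            left += 1
            p -= 1
        right = 0
        p = j
        while p < n and vm[p] == 0:
            right += 1
            p += 1
        runs.append({"start": i, "end": j, "len": j - i,
                     "ok": (j - i) <= tol and left >= flank and right >= flank})
        i = j

    bad_bounds = [(r["start"], r["end"]) for r in runs if not r["ok"]]

    for a in range(n):
        if vm[a] != 0:
            continue
        for b in range(a + window - 1, n):
            if vm[b] != 0:
                continue
            # interval [a, b] qualifies iff no disqualified run inside
            contains_bad = any(a <= s and e <= b + 1 for s, e in bad_bounds)
            if not contains_bad:
                nonwear[a : b + 1] = True
    return ~nonwear  # return wear labels, matching detect_nonwear


def classify_oracle(vm):
    """Literal cut-point lookup."""
    if vm <= 199:
        return "sedentary"
    if vm <= 2689:
        return "light"
    if vm <= 6166:
        return "moderate"
    return "vigorous"
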