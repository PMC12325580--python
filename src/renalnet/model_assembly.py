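"""RenalNet assembly, ablation variants, and exact parameter/FLOP accounting.

The full network is:

    input 224x224x3
    stem   Conv3x3(3->16)+BN+ReLU                    @ 224
    MCRT-1 (C=16)                                    @ 224   -> X1
    maxpool 2x2 ; trans Conv3x3(16->32)+BN+ReLU      @ 112
    MCRT-2 (C=32)                                    @ 112   -> X2
    maxpool 2x2 ; trans Conv3x3(32->64)+BN+ReLU      @ 56
    MCRT-3 (C=64)                                    @ 56    -> X3
    GCDL head on (X1, X2, X3)                        @ 56, 64 channels
    classifier  BN -> Conv1x1(64->32) -> BN -> global avg pool -> FC(32->4) -> softmax

Eight ablation variants are supported (CNN-1, GCNN-2 .. GCNN-7, Proposed);
their exact trainable-parameter totals are the only printed ground truth for
the head's internal widths, so :func:`solve_reference_config` recovers the
reference configuration from those totals by bounded integer search.

FLOP convention: 2 FLOPs per multiply-accumulate, convolution and fully
connected layers only (depthwise convolutions divide by the group count);
batch norm, activations, pooling and element-wise ops are excluded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core_blocks import MCRTBlock, mcrt_param_count
from .gcdl_blocks import ADSCBlock, AttentionGate, GCDLHead, StridedFusion
from .nn import (BatchNorm, Conv2d, Dense, GlobalAvgPool, MaxPool2x2, Module,
                 Tensor, softmax)

MIXED_RATIOS = (2, 4, 8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """One ablation row: which modules are active and the SE ratio policy."""
    name: str
    use_mcrt: bool
    use_gcdl: bool          # full head (fusion + ADSC + AM)
    use_adsc: bool
    use_am: bool
    ratios: tuple = MIXED_RATIOS

    @property
    def has_head(self) -> bool:
        return self.use_gcdl or self.use_adsc or self.use_am

    def validate(self):
        legal = {v.flags() for v in VARIANTS.values()}
        if self.flags() not in legal:
            near = min(VARIANTS.values(),
                       key=lambda v: sum(a != b for a, b in zip(v.flags(), self.flags())))
            raise ValueError(f"illegal variant flags {self.flags()}; nearest legal row is {near.name}")

    def flags(self):
        return (self.use_mcrt, self.use_gcdl, self.use_adsc, self.use_am, self.ratios)


VARIANTS: dict[str, VariantSpec] = {
    "CNN-1": VariantSpec("CNN-1", True, False, False, False),
    "GCNN-2": VariantSpec("GCNN-2", False, True, True, True),
    "GCNN-3": VariantSpec("GCNN-3", True, False, True, False),
    "GCNN-4": VariantSpec("GCNN-4", True, False, False, True),
    "GCNN-5": VariantSpec("GCNN-5", True, True, True, True, (2, 2, 2)),
    "GCNN-6": VariantSpec("GCNN-6", True, True, True, True, (4, 4, 4)),
    "GCNN-7": VariantSpec("GCNN-7", True, True, True, True, (8, 8, 8)),
    "Proposed": VariantSpec("Proposed", True, True, True, True),
}


@dataclass
class ModelConfig:
    """Widths and wiring of the reference model (see solve_reference_config)."""
    input_size: int = 224
    in_channels: int = 3
    num_classes: int = 4
    stage_widths: tuple = (16, 32, 64)
    fusion_widths: tuple = (6, 9, 16)
    merge_width: int = 45
    adsc_branch_width: int = 21
    am_hidden: int = 40
    classifier_width: int = 32

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("stage_widths", "fusion_widths"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class RenalNet(Module):
    """Configurable RenalNet; disabled MCRT blocks are identity passthroughs
    and a disabled head routes X3 straight into the classifier."""

    def __init__(self, spec: VariantSpec | str = "Proposed",
                 cfg: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        if isinstance(spec, str):
            spec = VARIANTS[spec]
        spec.validate()
        cfg = cfg or ModelConfig()
        self.spec, self.cfg = spec, cfg
        rng = np.random.default_rng(seed)
        w1, w2, w3 = cfg.stage_widths

        self.stem = Conv2d(cfg.in_channels, w1, rng=rng)
        self.stem_bn = BatchNorm(w1)
        self.mcrt1 = MCRTBlock(w1, spec.ratios, rng=rng) if spec.use_mcrt else None
        self.pool1 = MaxPool2x2()
        self.trans1 = Conv2d(w1, w2, rng=rng)
        self.trans1_bn = BatchNorm(w2)
        self.mcrt2 = MCRTBlock(w2, spec.ratios, rng=rng) if spec.use_mcrt else None
        self.pool2 = MaxPool2x2()
        self.trans2 = Conv2d(w2, w3, rng=rng)
        self.trans2_bn = BatchNorm(w3)
        self.mcrt3 = MCRTBlock(w3, spec.ratios, rng=rng) if spec.use_mcrt else None

        if spec.has_head:
            fusion = StridedFusion(cfg.fusion_widths, cfg.merge_width, cfg.stage_widths, rng=rng)
            gate = AttentionGate(cfg.merge_width, cfg.am_hidden, w3, rng=rng) if (
                spec.use_am or spec.use_gcdl) else None
            adsc = ADSCBlock(cfg.merge_width, cfg.adsc_branch_width, w3, rng=rng) if (
                spec.use_adsc or spec.use_gcdl) else None
            self.head = GCDLHead(fusion, gate, adsc,
                                 use_adsc=adsc is not None, use_am=gate is not None)
        else:
            self.head = None

        self.cls_bn1 = BatchNorm(w3)
        self.cls_conv = Conv2d(w3, cfg.classifier_width, kernel=1, rng=rng)
        self.cls_bn2 = BatchNorm(cfg.classifier_width)
        self.gap = GlobalAvgPool()
        self.fc = Dense(cfg.classifier_width, cfg.num_classes, rng=rng)

    # -- forward ------------------------------------------------------------
    def forward(self, x: Tensor, return_features: bool = False):
        x = self.stem_bn(self.stem(x)).relu()
        x1 = self.mcrt1(x) if self.mcrt1 else x
        x = self.trans1_bn(self.trans1(self.pool1(x1))).relu()
        x2 = self.mcrt2(x) if self.mcrt2 else x
        x = self.trans2_bn(self.trans2(self.pool2(x2))).relu()
        x3 = self.mcrt3(x) if self.mcrt3 else x
        feat = self.head(x1, x2, x3) if self.head else x3
        h = self.cls_bn2(self.cls_conv(self.cls_bn1(feat)))
        logits = self.fc(self.gap(h))
        if return_features:
            return logits, {"x1": x1, "x2": x2, "x3": x3, "feat": feat}
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for an (N,C,H,W) array (eval mode)."""
        self.eval()
        return softmax(self(Tensor(np.asarray(x, dtype=np.float32))).data)


def build_variant(spec: VariantSpec | str, cfg: ModelConfig | None = None,
                  seed: int = 0) -> RenalNet:
    return RenalNet(spec, cfg, seed=seed)


# ---------------------------------------------------------------------------
# Parameter ledger
# ---------------------------------------------------------------------------

@dataclass
class Ledger:
    """Per-layer accounting rows plus a grand total."""
    records: list = field(default_factory=list)   # (name, kind, shape, count)
    unit: str = "params"

    @property
    def total(self) -> int:
        return int(sum(r[3] for r in self.records))

    def subtotals(self) -> dict:
        out: dict[str, int] = {}
        for name, _, _, n in self.records:
            key = name.split(".")[0]
            out[key] = out.get(key, 0) + int(n)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=["layer", "kind", "shape", self.unit])
        total = pd.DataFrame([("TOTAL", "", "", self.total)], columns=df.columns)
        return pd.concat([df, total], ignore_index=True)


def count_params(model: Module) -> Ledger:
    """Exact trainable-parameter ledger: conv/dense weights and biases, plus
    two parameters per batch-norm channel; running statistics excluded."""
    led = Ledger(unit="params")
    for name, p in model.named_parameters():
        kind = ("batchnorm" if name.endswith((".gamma", ".beta"))
                else "bias" if name.endswith(".bias") else "weight")
        led.records.append((name, kind, "x".join(map(str, p.shape)), int(p.data.size)))
    return led


def ledger_report(ledger: Ledger, path) -> None:
    """Write a ledger as CSV (grand-total row included)."""
    ledger.to_frame().to_csv(path, index=False)


def read_ledger_total(path) -> int:
    df = pd.read_csv(path)
    return int(df[df["layer"] == "TOTAL"].iloc[0, 3])


# ---------------------------------------------------------------------------
# FLOP ledger
# ---------------------------------------------------------------------------

def _conv_macs(layer: Conv2d, out_hw: int) -> int:
    return out_hw * out_hw * layer.kernel ** 2 * (layer.in_ch // layer.groups) * layer.out_ch


def count_flops(model: RenalNet, input_size: int | None = None) -> Ledger:
    """FLOP ledger for one forward pass: 2 FLOPs per MAC, conv + FC only."""
    cfg = model.cfg
    S = input_size or cfg.input_size
    led = Ledger(unit="flops")

    def add_conv(name, layer, out_hw):
        led.records.append((name, "conv", f"{out_hw}x{out_hw}x{layer.out_ch}",
                            2 * _conv_macs(layer, out_hw)))

    def add_dense(name, layer):
        led.records.append((name, "dense", f"{layer.in_f}->{layer.out_f}",
                            2 * layer.in_f * layer.out_f))

    def add_mcrt(name, block, out_hw):
        if block is None:
            return
        for i, (path, se) in enumerate(zip(block.paths, block.se_units)):
            add_conv(f"{name}.path{i}.conv", path.conv, out_hw)
            add_dense(f"{name}.se{i}.fc1", se.fc1)
            add_dense(f"{name}.se{i}.fc2", se.fc2)

    s1, s2, s3 = S, S // 2, S // 4
    add_conv("stem", model.stem, s1)
    add_mcrt("mcrt1", model.mcrt1, s1)
    add_conv("trans1", model.trans1, s2)
    add_mcrt("mcrt2", model.mcrt2, s2)
    add_conv("trans2", model.trans2, s3)
    add_mcrt("mcrt3", model.mcrt3, s3)
    if model.head is not None:
        fu = model.head.fusion
        add_conv("head.fusion.k1", fu.k1, s3)
        add_conv("head.fusion.k2", fu.k2, s3)
        add_conv("head.fusion.k3", fu.k3, s3)
        add_conv("head.fusion.k4_dw", fu.k4_dw, s3)
        add_conv("head.fusion.k4_pw", fu.k4_pw, s3)
        if model.head.use_am:
            add_dense("head.gate.fc1", model.head.gate.fc1)
            add_dense("head.gate.fc2", model.head.gate.fc2)
        if model.head.use_adsc:
            ad = model.head.adsc
            for i, (dw, pw) in enumerate(zip(ad.dw, ad.pw)):
                add_conv(f"head.adsc.dw{i}", dw, s3)
                add_conv(f"head.adsc.pw{i}", pw, s3)
            add_conv("head.adsc.proj", ad.proj, s3)
    add_conv("cls_conv", model.cls_conv, s3)
    add_dense("fc", model.fc)
    return led


def gflops(ledger: Ledger) -> float:
    """Grand total in units of 1e9, rounded to three significant figures."""
    return float(f"{ledger.total / 1e9:.3g}")


# ---------------------------------------------------------------------------
# Closed-form closures and the reference-configuration solver
# ---------------------------------------------------------------------------

def stem_head_param_count(cfg: ModelConfig) -> int:
    """Stem + two transitions + classifier head, closed form."""
    w1, w2, w3 = cfg.stage_widths
    cw, k = cfg.classifier_width, cfg.num_classes
    stem = 9 * cfg.in_channels * w1 + w1 + 2 * w1
    t1 = 9 * w1 * w2 + w2 + 2 * w2
    t2 = 9 * w2 * w3 + w3 + 2 * w3
    head = 2 * w3 + (w3 * cw + cw) + 2 * cw + (cw * k + k)
    return stem + t1 + t2 + head


def gcdl_param_counts(cfg: ModelConfig) -> dict:
    """Exact head sub-budgets under the package's bias/BN conventions."""
    F1, F2, F3 = cfg.fusion_widths
    Cf, Wb, h = cfg.merge_width, cfg.adsc_branch_width, cfg.am_hidden
    w1, w2, w3 = cfg.stage_widths
    Ct = F1 + F2 + F3
    shared = (9 * w1 * F1 + 3 * F1 + 9 * w2 * F2 + 3 * F2 + 9 * w3 * F3 + 3 * F3
              + 9 * Ct + Ct          # depthwise 3x3 + bias
              + Ct * Cf              # pointwise, no bias
              + 2 * Cf)              # BN
    adsc = 4 * (9 * Cf + Cf * Wb + 2 * Wb) + (4 * Wb * w3 + w3) + 2 * w3
    am = (Cf * h + h) + (h * w3 + w3) + 2 * w3
    return {"shared": shared, "adsc": adsc, "am": am, "total": shared + adsc + am}


def expected_variant_total(spec: VariantSpec, cfg: ModelConfig) -> int:
    """Closed-form trainable-parameter total for a variant."""
    total = stem_head_param_count(cfg)
    if spec.use_mcrt:
        total += sum(mcrt_param_count(C, spec.ratios) for C in cfg.stage_widths)
    sub = gcdl_param_counts(cfg)
    if spec.has_head:
        total += sub["shared"]
        if spec.use_adsc or spec.use_gcdl:
            total += sub["adsc"]
        if spec.use_am or spec.use_gcdl:
            total += sub["am"]
    return total


class ConfigSolveError(RuntimeError):
    pass


def solve_reference_config(ledger_targets: dict | None = None,
                           f_bounds=(4, 64), cf_bounds=(16, 128),
                           wb_bounds=(4, 64), hidden_bounds=(4, 128)) -> ModelConfig:
    """Recover the reference configuration from the printed variant totals.

    The head's internal widths are never printed; the eight variant totals
    are.  Derived budgets (by subtraction / inclusion-exclusion over the
    targets): MCRT total, stem+classifier closure, and the head split into
    shared fusion, ADSC-proper and attention-proper.  The solver then searches
    integer widths, under the package's fixed bias/BN conventions, for an
    exact simultaneous match; ties among fusion widths are broken by
    preferring non-decreasing widths and the largest stage-3 share.

    Raises :class:`ConfigSolveError` with the best residuals when no exact
    solution exists in the bounds.
    """
    t = ledger_targets or {"Proposed": 213174, "CNN-1": 182886, "GCNN-2": 56500,
                           "GCNN-3": 208582, "GCNN-4": 202038,
                           "GCNN-5": 219964, "GCNN-6": 211816, "GCNN-7": 207742}
    mcrt_budget = t["Proposed"] - t["GCNN-2"]
    stem_head_budget = t["CNN-1"] - mcrt_budget
    head_budget = t["Proposed"] - t["CNN-1"]
    adsc_budget = t["Proposed"] - t["GCNN-4"]     # GCNN-4 lacks only ADSC
    am_budget = t["Proposed"] - t["GCNN-3"]       # GCNN-3 lacks only AM
    shared_budget = head_budget - adsc_budget - am_budget

    base = ModelConfig()
    closed_mcrt = sum(mcrt_param_count(C, MIXED_RATIOS) for C in base.stage_widths)
    if closed_mcrt != mcrt_budget:
        raise ConfigSolveError(f"MCRT closure mismatch: closed form {closed_mcrt} vs "
                               f"derived budget {mcrt_budget}")
    if stem_head_param_count(base) != stem_head_budget:
        raise ConfigSolveError(f"stem+classifier closure mismatch: "
                               f"{stem_head_param_count(base)} vs {stem_head_budget}")

    w1, w2, w3 = base.stage_widths
    best = None
    for Cf in range(cf_bounds[0], cf_bounds[1] + 1):
        # attention gate: (Cf*h + h) + (h*64 + 64) + BN(64) = am_budget
        num = am_budget - w3 - 2 * w3
        if num % (Cf + 1 + w3):
            continue
        h = num // (Cf + 1 + w3)
        if not (hidden_bounds[0] <= h <= hidden_bounds[1]):
            continue
        # ADSC: 4*(9Cf + Cf*Wb + 2Wb) + 4*Wb*64 + 64 + 128 = adsc_budget
        rem = adsc_budget - 36 * Cf - w3 - 2 * w3
        den = 4 * Cf + 8 + 4 * w3
        if rem % den:
            continue
        Wb = rem // den
        if not (wb_bounds[0] <= Wb <= wb_bounds[1]):
            continue
        # shared fusion: solve (F1, F2, F3)
        for F3 in range(f_bounds[1], f_bounds[0] - 1, -1):
            for F2 in range(F3, f_bounds[0] - 1, -1):
                r = (shared_budget - 2 * Cf
                     - (9 * w3 + 3 + 9 + 1 + Cf) * F3
                     - (9 * w2 + 3 + 9 + 1 + Cf) * F2)
                den1 = 9 * w1 + 3 + 9 + 1 + Cf
                if r <= 0 or r % den1:
                    continue
                F1 = r // den1
                if f_bounds[0] <= F1 <= F2:
                    cand = dataclasses.replace(base, fusion_widths=(F1, F2, F3),
                                               merge_width=Cf, adsc_branch_width=Wb,
                                               am_hidden=h)
                    if gcdl_param_counts(cand)["total"] == head_budget:
                        if best is None:
                            best = cand
    if best is None:
        raise ConfigSolveError(
            "no exact head configuration in bounds; derived budgets were "
            f"shared={shared_budget}, adsc={adsc_budget}, am={am_budget}")

    # every printed row must be reproduced simultaneously
    for name, spec in VARIANTS.items():
        got = expected_variant_total(spec, best)
        if got != t[name]:
            raise ConfigSolveError(f"solved config fails row {name}: {got} != {t[name]}")
    return best
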