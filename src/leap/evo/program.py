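"""Linear programs over registers, features and constants.

A program is an ordered list of instructions; each applies one palette
function to operands drawn from the registers (all initialised to 0), the
feature row, or the program's constant pool, and stores the result in a
destination register. Register 0 after the last instruction is the score;
``score > 0`` calls the positive (lung cancer) class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .palette import PALETTE, guard, guard_clip

# operand kinds
REG, FEAT, CONST = 0, 1, 2

_KIND_PROBS = (0.30, 0.50, 0.20)  # register / feature / constant

# Proposal weights over the palette for random/mutated instructions. All 48
# functions stay reachable, but arithmetic is proposed far more often: useful
# programs are dominated by additive feature combinations, and diluting
# proposals uniformly over the exotic tail starves the search of them.
_FUNC_WEIGHTS = np.array(
    [
        {
            "add": 8.0,
            "sub": 8.0,
            "mul": 3.0,
            "div": 3.0,
            "fma": 3.0,
            "mean2": 2.0,
            "min": 2.0,
            "max": 2.0,
            "absdiff": 2.0,
            "if_then_else": 2.0,
            "gt": 2.0,
            "lt": 2.0,
        }.get(f.name, 1.0)
        for f in PALETTE
    ]
)
_FUNC_WEIGHTS /= _FUNC_WEIGHTS.sum()

#: probability that a random instruction reads its own destination register,
#: seeding read-modify-write accumulator chains that extend well under both
#: insertion mutation and tail crossover
ACCUMULATOR_PROB = 0.5


@dataclass(frozen=True)
class Instruction:
    func_id: int
    dest: int
    operands: tuple  # of (kind, index) pairs, len == arity

    def __post_init__(self):
        if len(self.operands) != PALETTE[self.func_id].arity:
            raise ValueError(
                f"{PALETTE[self.func_id].name}: arity "
                f"{PALETTE[self.func_id].arity} != {len(self.operands)} operands"
            )


@dataclass
class Program:
    instructions: list = field(default_factory=list)
    consts: list = field(default_factory=list)
    n_registers: int = 8

    def __len__(self) -> int:
        return len(self.instructions)

    def referenced_features(self) -> set:
        return {
            idx
            for ins in self.instructions
            for kind, idx in ins.operands
            if kind == FEAT
        }

    def to_dict(self) -> dict:
        return {
            "instructions": [
                [ins.func_id, ins.dest, [list(op) for op in ins.operands]]
                for ins in self.instructions
            ],
            "consts": [float(c) for c in self.consts],
            "n_registers": self.n_registers,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Program":
        return cls(
            instructions=[
                Instruction(fid, dest, tuple((k, i) for k, i in ops))
                for fid, dest, ops in data["instructions"]
            ],
            consts=list(data["consts"]),
            n_registers=int(data["n_registers"]),
        )

    def fingerprint(self) -> tuple:
        return (
            tuple(
                (ins.func_id, ins.dest, ins.operands) for ins in self.instructions
            ),
            tuple(self.consts),
        )


def execute(program: Program, X) -> np.ndarray:
    """Run a program over rows of ``X`` (n x p); returns the n scores.

    Registers start at 0; every instruction result is clamped and
    NaN/Inf-guarded, so the output is finite for any finite input.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    regs: list = [0.0] * program.n_registers
    consts = program.consts
    for ins in program.instructions:
        vals = []
        for kind, idx in ins.operands:
            if kind == REG:
                vals.append(regs[idx])
            elif kind == FEAT:
                vals.append(X[:, idx])
            else:
                vals.append(consts[idx])
        spec = PALETTE[ins.func_id]
        g = guard if spec.needs_nan_guard else guard_clip
        regs[ins.dest] = g(spec.fn(*vals))
    out = regs[0]
    if np.ndim(out) == 0:
        return np.full(n, float(out))
    return np.asarray(out, dtype=float)


def classify(program: Program, X) -> np.ndarray:
    return execute(program, X) > 0


def effective_mask(program: Program) -> np.ndarray:
    """Mark instructions whose result can reach register 0 (structural
    introns excluded). Computed by a backward register-liveness pass; running
    only the marked instructions yields the identical output."""
    mask = np.zeros(len(program.instructions), dtype=bool)
    needed = {0}
    for i in range(len(program.instructions) - 1, -1, -1):
        ins = program.instructions[i]
        if ins.dest in needed:
            mask[i] = True
            needed.discard(ins.dest)
            needed.update(idx for kind, idx in ins.operands if kind == REG)
    return mask


def execute_effective(program: Program, X) -> np.ndarray:
    """As :func:`execute` but skipping structural introns (same result)."""
    mask = effective_mask(program)
    if mask.all():
        return execute(program, X)
    trimmed = Program(
        [ins for ins, m in zip(program.instructions, mask) if m],
        program.consts,
        program.n_registers,
    )
    return execute(trimmed, X)


def _random_operand(n_features: int, n_registers: int, n_consts: int, rng) -> tuple:
    kind = rng.choice(3, p=_KIND_PROBS)
    if kind == CONST and n_consts == 0:
        kind = FEAT
    if kind == REG:
        return (REG, int(rng.integers(n_registers)))
    if kind == FEAT:
        return (FEAT, int(rng.integers(n_features)))
    return (CONST, int(rng.integers(n_consts)))


def random_instruction(n_features: int, n_registers: int, n_consts: int, rng) -> Instruction:
    fid = int(rng.choice(len(PALETTE), p=_FUNC_WEIGHTS))
    ops = [
        _random_operand(n_features, n_registers, n_consts, rng)
        for _ in range(PALETTE[fid].arity)
    ]
    dest = int(rng.integers(n_registers))
    if rng.random() < ACCUMULATOR_PROB:
        ops[int(rng.integers(len(ops)))] = (REG, dest)
    return Instruction(fid, dest, tuple(ops))


def random_program(n_features: int, cfg, rng) -> Program:
    """Uniform-length random program with constants ~ N(0, const_sd)."""
    length = int(rng.integers(cfg.min_len, cfg.init_max_len + 1))
    consts = list(rng.normal(0.0, cfg.const_sd, size=cfg.n_consts))
    instrs = [
        random_instruction(n_features, cfg.n_registers, cfg.n_consts, rng)
        for _ in range(length)
    ]
    return Program(instrs, consts, cfg.n_registers)


def _compact_consts(instructions: list, consts: list) -> tuple[list, list]:
    """Drop unused constants, remapping operand indices."""
    used: dict[int, int] = {}
    new_instr = []
    for ins in instructions:
        ops = []
        for kind, idx in ins.operands:
            if kind == CONST:
                if idx not in used:
                    used[idx] = len(used)
                ops.append((CONST, used[idx]))
            else:
                ops.append((kind, idx))
        new_instr.append(Instruction(ins.func_id, ins.dest, tuple(ops)))
    new_consts = [consts[i] for i in used]
    return new_instr, new_consts


def mutate(program: Program, n_features: int, cfg, rng) -> Program:
    """Copy-with-variation: per-instruction point mutations plus optional
    insertion/deletion, and Gaussian perturbation of one constant."""
    instrs = list(program.instructions)
    consts = list(program.consts)
    n_consts = len(consts)
    n_regs = program.n_registers  # offspring keep their parent's register file

    # point mutations concentrate on effective code: edits to structural
    # introns are fitness-neutral and waste offspring evaluations
    eff = effective_mask(program)
    for i in range(len(instrs)):
        rate = cfg.mutation_rate * (2.5 if eff[i] else 0.3)
        if rng.random() >= rate:
            continue
        ins = instrs[i]
        kind = rng.integers(3)
        if kind == 0:  # replace the whole instruction
            instrs[i] = random_instruction(n_features, n_regs, n_consts, rng)
        elif kind == 1:  # rewire one operand
            ops = list(ins.operands)
            j = int(rng.integers(len(ops)))
            ops[j] = _random_operand(n_features, n_regs, n_consts, rng)
            instrs[i] = Instruction(ins.func_id, ins.dest, tuple(ops))
        else:  # retarget the destination register
            instrs[i] = Instruction(
                ins.func_id, int(rng.integers(n_regs)), ins.operands
            )

    if consts and rng.random() < cfg.const_mut_prob:
        j = int(rng.integers(len(consts)))
        consts[j] += rng.normal(0.0, 0.3 * cfg.const_sd)

    if len(instrs) < cfg.max_len and rng.random() < cfg.insert_prob:
        pos = int(rng.integers(len(instrs) + 1))
        instrs.insert(
            pos, random_instruction(n_features, n_regs, n_consts, rng)
        )
    if len(instrs) > cfg.min_len and rng.random() < cfg.delete_prob:
        del instrs[int(rng.integers(len(instrs)))]

    return Program(instrs, consts, n_regs)


def crossover(a: Program, b: Program, cfg, rng) -> tuple[Program, Program]:
    """One-point linear crossover exchanging instruction tails.

    Cut points are sampled so both children respect the length bounds; if no
    valid cut exists the parents are returned as (copied) children.
    """
    la, lb = len(a), len(b)
    ia = ib = -1
    for _ in range(8):
        cand = int(rng.integers(la + 1))
        # child lengths: ia + (lb - ib) and ib + (la - ia), both within bounds
        lo = max(0, cand + lb - cfg.max_len, cfg.min_len - la + cand)
        hi = min(lb, cand + lb - cfg.min_len, cfg.max_len - la + cand)
        if lo <= hi:
            ia, ib = cand, int(rng.integers(lo, hi + 1))
            break
    if ia < 0:
        return (
            Program(list(a.instructions), list(a.consts), a.n_registers),
            Program(list(b.instructions), list(b.consts), b.n_registers),
        )

    n_regs = max(a.n_registers, b.n_registers)

    def child(head, head_c, tail, tail_c):
        shifted = []
        off = len(head_c)
        for ins in tail:
            ops = tuple(
                (CONST, idx + off) if kind == CONST else (kind, idx)
                for kind, idx in ins.operands
            )
            shifted.append(Instruction(ins.func_id, ins.dest, ops))
        instrs, consts = _compact_consts(list(head) + shifted, list(head_c) + list(tail_c))
        return Program(instrs, consts, n_regs)

    c1 = child(a.instructions[:ia], a.consts, b.instructions[ib:], b.consts)
    c2 = child(b.instructions[:ib], b.consts, a.instructions[ia:], a.consts)
    return c1, c2
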