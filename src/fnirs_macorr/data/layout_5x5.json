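{
 "channels": [
  {
   "id": 1,
   "optode_a": "T1",
   "optode_b": "R1"
  },
  {
   "id": 2,
   "optode_a": "R1",
   "optode_b": "T2"
  },
  {
   "id": 3,
   "optode_a": "T2",
   "optode_b": "R2"
  },
  {
   "id": 4,
   "optode_a": "R2",
   "optode_b": "T3"
  },
  {
   "id": 5,
   "optode_a": "T1",
   "optode_b": "R3"
  },
  {
   "id": 6,
   "optode_a": "R1",
   "optode_b": "T4"
  },
  {
   "id": 7,
   "optode_a": "T2",
   "optode_b": "R4"
  },
  {
   "id": 8,
   "optode_a": "R2",
   "optode_b": "T5"
  },
  {
   "id": 9,
   "optode_a": "T3",
   "optode_b": "R5"
  },
  {
   "id": 10,
   "optode_a": "R3",
   "optode_b": "T4"
  },
  {
   "id": 11,
   "optode_a": "T4",
   "optode_b": "R4"
  },
  {
   "id": 12,
   "optode_a": "R4",
   "optode_b": "T5"
  },
  {
   "id": 13,
   "optode_a": "T5",
   "optode_b": "R5"
  },
  {
   "id": 14,
   "optode_a": "R3",
   "optode_b": "T6"
  },
  {
   "id": 15,
   "optode_a": "T4",
   "optode_b": "R6"
  },
  {
   "id": 16,
   "optode_a": "R4",
   "optode_b": "T7"
  },
  {
   "id": 17,
   "optode_a": "T5",
   "optode_b": "R7"
  },
  {
   "id": 18,
   "optode_a": "R5",
   "optode_b": "T8"
  },
  {
   "id": 19,
   "optode_a": "T6",
   "optode_b": "R6"
  },
  {
   "id": 20,
   "optode_a": "R6",
   "optode_b": "T7"
  },
  {
   "id": 21,
   "optode_a": "T7",
   "optode_b": "R7"
  },
  {
   "id": 22,
   "optode_a": "R7",
   "optode_b": "T8"
  },
  {
   "id": 23,
   "optode_a": "T6",
   "optode_b": "R8"
  },
  {
   "id": 24,
   "optode_a": "R6",
   "optode_b": "T9"
  },
  {
   "id": 25,
   "optode_a": "T7",
   "optode_b": "R9"
  },
  {
   "id": 26,
   "optode_a": "R7",
   "optode_b": "T10"
  },
  {
   "id": 27,
   "optode_a": "T8",
   "optode_b": "R10"
  },
  {
   "id": 28,
   "optode_a": "R8",
   "optode_b": "T9"
  },
  {
   "id": 29,
   "optode_a": "T9",
   "optode_b": "R9"
  },
  {
   "id": 30,
   "optode_a": "R9",
   "optode_b": "T10"
  },
  {
   "id": 31,
   "optode_a": "T10",
   "optode_b": "R10"
  },
  {
   "id": 32,
   "optode_a": "R8",
   "optode_b": "T11"
  },
  {
   "id": 33,
   "optode_a": "T9",
   "optode_b": "R11"
  },
  {
   "id": 34,
   "optode_a": "R9",
   "optode_b": "T12"
  },
  {
   "id": 35,
   "optode_a": "T10",
   "optode_b": "R12"
  },
  {
   "id": 36,
   "optode_a": "R10",
   "optode_b": "T13"
  },
  {
   "id": 37,
   "optode_a": "T11",
   "optode_b": "R11"
  },
  {
   "id": 38,
   "optode_a": "R11",
   "optode_b": "T12"
  },
  {
   "id": 39,
   "optode_a": "T12",
   "optode_b": "R12"
  },
  {
   "id": 40,
   "optode_a": "R12",
   "optode_b": "T13"
  }
 ],
 "grid_cols": 5,
 "grid_rows": 5,
 "optodes": [
  {
   "col": 1,
   "id": "T1",
   "kind": "T",
   "row": 1
  },
  {
   "col": 2,
   "id": "R1",
   "kind": "R",
   "row": 1
  },
  {
   "col": 3,
   "id": "T2",
   "kind": "T",
   "row": 1
  },
  {
   "col": 4,
   "id": "R2",
   "kind": "R",
   "row": 1
  },
  {
   "col": 5,
   "id": "T3",
   "kind": "T",
   "row": 1
  },
  {
   "col": 1,
   "id": "R3",
   "kind": "R",
   "row": 2
  },
  {
   "col": 2,
   "id": "T4",
   "kind": "T",
   "row": 2
  },
  {
   "col": 3,
   "id": "R4",
   "kind": "R",
   "row": 2
  },
  {
   "col": 4,
   "id": "T5",
   "kind": "T",
   "row": 2
  },
  {
   "col": 5,
   "id": "R5",
   "kind": "R",
   "row": 2
  },
  {
   "col": 1,
   "id": "T6",
   "kind": "T",
   "row": 3
  },
  {
   "col": 2,
   "id": "R6",
   "kind": "R",
   "row": 3
  },
  {
   "col": 3,
   "id": "T7",
   "kind": "T",
   "row": 3
  },
  {
   "col": 4,
   "id": "R7",
   "kind": "R",
   "row": 3
  },
  {
   "col": 5,
   "id": "T8",
   "kind": "T",
   "row": 3
  },
  {
   "col": 1,
   "id": "R8",
   "kind": "R",
   "row": 4
  },
  {
   "col": 2,
   "id": "T9",
   "kind": "T",
   "row": 4
  },
  {
   "col": 3,
   "id": "R9",
   "kind": "R",
   "row": 4
  },
  {
   "col": 4,
   "id": "T10",
   "kind": "T",
   "row": 4
  },
  {
   "col": 5,
   "id": "R10",
   "kind": "R",
   "row": 4
  },
  {
   "col": 1,
   "id": "T11",
   "kind": "T",
   "row": 5
  },
  {
   "col": 2,
   "id": "R11",
   "kind": "R",
   "row": 5
  },
  {
   "col": 3,
   "id": "T12",
   "kind": "T",
   "row": 5
  },
  {
   "col": 4,
   "id": "R12",
   "kind": "R",
   "row": 5
  },
  {
   "col": 5,
   "id": "T13",
   "kind": "T",
   "row": 5
  }
 ],
 "spacing_cm": 3.0
}
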