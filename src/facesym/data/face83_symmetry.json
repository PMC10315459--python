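{
 "pairs": [
  [
   1,
   2
  ],
  [
   3,
   4
  ],
  [
   5,
   6
  ],
  [
   7,
   8
  ],
  [
   9,
   10
  ],
  [
   11,
   12
  ],
  [
   13,
   14
  ],
  [
   15,
   16
  ],
  [
   17,
   18
  ],
  [
   19,
   27
  ],
  [
   20,
   28
  ],
  [
   21,
   29
  ],
  [
   22,
   30
  ],
  [
   23,
   31
  ],
  [
   24,
   32
  ],
  [
   25,
   33
  ],
  [
   26,
   34
  ],
  [
   35,
   45
  ],
  [
   36,
   46
  ],
  [
   37,
   47
  ],
  [
   38,
   48
  ],
  [
   39,
   49
  ],
  [
   40,
   50
  ],
  [
   41,
   51
  ],
  [
   42,
   52
  ],
  [
   43,
   53
  ],
  [
   44,
   54
  ],
  [
   57,
   61
  ],
  [
   58,
   62
  ],
  [
   59,
   63
  ],
  [
   60,
   64
  ],
  [
   67,
   75
  ],
  [
   68,
   76
  ],
  [
   69,
   77
  ],
  [
   70,
   78
  ],
  [
   71,
   79
  ],
  [
   72,
   80
  ],
  [
   73,
   81
  ],
  [
   74,
   82
  ]
 ],
 "midline": [
  0,
  55,
  56,
  65,
  66
 ],
 "axis": "x",
 "index_base": 0
}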