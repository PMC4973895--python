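{
 "advances": {
  " ": 0.318,
  "!": 0.401,
  "\"": 0.46,
  "#": 0.838,
  "$": 0.636,
  "%": 0.95,
  "&": 0.78,
  "'": 0.275,
  "(": 0.39,
  ")": 0.39,
  "*": 0.5,
  "+": 0.838,
  ",": 0.318,
  "-": 0.361,
  ".": 0.318,
  "/": 0.337,
  "0": 0.636,
  "1": 0.636,
  "2": 0.636,
  "3": 0.636,
  "4": 0.636,
  "5": 0.636,
  "6": 0.636,
  "7": 0.636,
  "8": 0.636,
  "9": 0.636,
  ":": 0.337,
  ";": 0.337,
  "<": 0.838,
  "=": 0.838,
  ">": 0.838,
  "?": 0.531,
  "@": 1.0,
  "A": 0.684,
  "B": 0.686,
  "C": 0.698,
  "D": 0.77,
  "E": 0.632,
  "F": 0.575,
  "G": 0.775,
  "H": 0.752,
  "I": 0.295,
  "J": 0.295,
  "K": 0.656,
  "L": 0.557,
  "M": 0.863,
  "N": 0.748,
  "O": 0.787,
  "P": 0.603,
  "Q": 0.787,
  "R": 0.695,
  "S": 0.635,
  "T": 0.611,
  "U": 0.732,
  "V": 0.684,
  "W": 0.989,
  "X": 0.685,
  "Y": 0.611,
  "Z": 0.685,
  "[": 0.39,
  "\\": 0.337,
  "]": 0.39,
  "^": 0.838,
  "_": 0.5,
  "`": 0.5,
  "a": 0.613,
  "b": 0.635,
  "c": 0.55,
  "d": 0.635,
  "e": 0.615,
  "f": 0.352,
  "g": 0.635,
  "h": 0.634,
  "i": 0.278,
  "j": 0.278,
  "k": 0.579,
  "l": 0.278,
  "m": 0.974,
  "n": 0.634,
  "o": 0.612,
  "p": 0.635,
  "q": 0.635,
  "r": 0.411,
  "s": 0.521,
  "t": 0.392,
  "u": 0.634,
  "v": 0.592,
  "w": 0.818,
  "x": 0.592,
  "y": 0.592,
  "z": 0.525,
  "{": 0.636,
  "|": 0.337,
  "}": 0.636,
  "~": 0.838
 },
 "font": "DejaVu Sans",
 "units": "advance width per 1 px of font size"
}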