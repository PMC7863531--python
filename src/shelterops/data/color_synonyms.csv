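token,category
black,black
brown,brown
chocolate,brown
tan,brown
fawn,brown
red,brown
liver,brown
gold,brown
golden,brown
yellow,brown
orange,brown
buff,brown
sable,brown
brindle,brown
apricot,brown
seal,brown
blue,blue
gray,blue
grey,blue
silver,blue
slate,blue
lilac,blue
white,white
cream,white
ivory,white
calico,multicolor
tortie,multicolor
tortoiseshell,multicolor
torbie,multicolor
tricolor,multicolor
tricolored,multicolor
merle,multicolor
tabby,multicolor
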