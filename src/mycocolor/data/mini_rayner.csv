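Color,L,A,B,HueGroup,ClassOfCompounds,R,G,B
Dark Delft Blue,25,-50,-50,blue,melanin,0,0.30900912630905486,0.53194563324429989
Bremen Blue,75,-50,-50,blue,,0,0.8324819760754214,1
Amethyst Violet,25,50,-50,purple,,0.34920536051308182,0.07753680078215,0.53599191748056563
Light Phlox Purple,75,50,-50,purple-blue,,0.90035396347101448,0.5998218929824124,1
Calliste Green,25,-50,50,green,xylindein,0,0.28842060101207057,0
Naples Yellow,75,-50,50,yellow,carotenoid,0.44010914505983217,0.80782266893700017,0.33929400117127079
Mars Yellow,25,50,50,yellow-red,naphthoquinone;polyketide,0.50818367186334512,0,0
Olive-Ocher,75,50,50,yellow,azaphilones,1,0.56123130127356757,0.37164973071352564
Plumbeous Black,26.982917772686811,0,0,blue,melanin,0.25,0.25,0.25
Scarlet Red,45.795705238282324,50.931876266128548,28.574179626829654,red,naphthoquinone,0.75,0.25,0.25
Pea Green,68.618813774306446,-59.140494320363167,52.293616617126148,green,,0.25,0.75,0.25
Sulphur Yellow,75.356702058063277,-15.515738289780312,61.428014744701542,yellow,carotenoid,0.75,0.75,0.25
Cornflower Blue,34.986637007200514,40.110011738259203,-66.761901291171384,blue,,0.25,0.25,0.75
Mallow Purple,50.123605266404923,65.691846334910096,-41.591640041875991,purple,,0.75,0.25,0.75
Glaucous Blue,71.023389966964118,-33.872908657980872,-10.182979644384659,blue-green,xylindein,0.25,0.75,0.75
Pallid Mouse Gray,77.431371890244833,0,0,red,,0.75,0.75,0.75
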